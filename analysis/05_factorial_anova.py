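"""Factorial shape-ANOVA: anatomical position x taxon.

Sequential sums of squares on the jointly superimposed coordinates with
residual-randomization permutation p-values.  A significant interaction
means taxonomic differences vary along the tooth row, motivating the
per-tooth discriminant analyses.
"""

from common import run_config

from enamelgmm.pipeline import cmd_anova


def main() -> None:
    table = cmd_anova(run_config())
    print(table.round(4).to_string())


if __name__ == "__main__":
    main()
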