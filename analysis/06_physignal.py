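"""Phylogenetic signal in tooth shape.

Per tooth: species mean shapes of the 10 tree species (re-superimposed),
the multivariate K statistic with a 1000-permutation test against the
molecular tree, and phylomorphospace coordinates (tips + squared-change-
parsimony internal nodes on PC1/PC2).  Tables land under results/.
"""

from common import run_config

from enamelgmm.pipeline import cmd_physignal


def main() -> None:
    table = cmd_physignal(run_config())
    print(table.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
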