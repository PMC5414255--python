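"""Taxonomic discrimination per tooth position.

For each tooth: MANOVA (Pillai's trace) over the 15 taxa on the retained
PCs, and a twofold cross-validated CVA classification (CCV).  Writes the
per-tooth table and confusion matrices under results/.
"""

from common import run_config

from enamelgmm.pipeline import cmd_classify


def main() -> None:
    table = cmd_classify(run_config())
    print(table.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
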