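"""Anatomical discrimination: can an isolated tooth be placed in the row?

Four-class CVA (P3/P4/M1/M2) on the jointly superimposed dataset with
twofold cross-validated classification.  Writes the anatomy CCV report and
confusion matrix under results/.
"""

import json

from common import run_config

from enamelgmm.pipeline import cmd_anatomy


def main() -> None:
    out = cmd_anatomy(run_config())
    print(f"anatomical CCV (per-round mean): {out['ccv']:.2f}%")
    print(f"anatomical CCV (modal assignment): {out['ccv_modal']:.2f}%")
    print("per tooth:", json.dumps({k: round(v, 1) for k, v in out["ccv_per_group"].items()}))


if __name__ == "__main__":
    main()
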