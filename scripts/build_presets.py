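"""Regenerate the shipped optimal-method coefficient table.

Runs the variance-bounded stability optimizer for (s, eps) in
{3, 5} x {0.1, 0.25, 0.5} and writes src/rkleap/data/optimal_tableaus.json.
"""

import json
from pathlib import Path

from rkleap.optimize import optimize_polynomial

OUT = Path(__file__).resolve().parent.parent / "src" / "rkleap" / "data" / "optimal_tableaus.json"


def main() -> None:
    table = {}
    for s in (3, 5):
        for eps in (0.1, 0.25, 0.5):
            res = optimize_polynomial(s, eps)
            name = f"rk-tauleap-s{s}-eps{eps}"
            table[name] = {
                "s": s,
                "eps": eps,
                "r": list(res.poly.r),
                "l": res.l,
            }
            print(f"{name}: l = {res.l:.5f}")
    OUT.write_text(json.dumps(table, indent=1) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
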