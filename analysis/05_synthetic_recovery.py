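"""Planted-optimum recovery of the full pipeline on synthetic experiments.

Generates study-shaped data from an additive truth with a known optimal
combination and measures how often GRA + S/N main effects recover it,
across noise levels. Key finding: recovery is certain without noise,
remains high at realistic noise, and collapses to the 1/3-per-factor
chance level when the planted effects are removed.
"""

from pathlib import Path

import pandas as pd

import taguchigra as tg
from taguchigra.design import format_combination
from taguchigra.synthetic import planted_optimum, with_effect_scale

OUT = Path(__file__).resolve().parent.parent / "results"
REPETITIONS = 200


def main() -> None:
    OUT.mkdir(exist_ok=True)
    base = tg.default_config(seed=2026)
    print(f"planted optimum: {format_combination(planted_optimum(base))}")
    rows = []
    for label, config in [
        ("no noise", tg.default_config(seed=2026, sigma_scale=0.0)),
        ("default noise", base),
        ("3x noise", tg.default_config(seed=2026, sigma_scale=3.0)),
        ("null (no effects)", with_effect_scale(base, 0.0)),
    ]:
        result = tg.recovery_experiment(config, REPETITIONS)
        rows.append({"condition": label, "joint": result.joint, **result.per_factor.to_dict()})
        print(f"  {label:>18}: joint {result.joint:.3f}, per-factor "
              + ", ".join(f"{k}={v:.3f}" for k, v in result.per_factor.items()))
    table = pd.DataFrame(rows).set_index("condition")
    table.to_csv(OUT / "synthetic_recovery.csv", float_format="%.3f")
    print(f"({REPETITIONS} repetitions per condition; chance level per factor is 1/3)")
    print(f"wrote {OUT / 'synthetic_recovery.csv'}")


if __name__ == "__main__":
    main()
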