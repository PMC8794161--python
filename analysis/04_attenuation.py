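#!/usr/bin/env python
"""Quantify how binomial trial noise attenuates the recoverable correlation.

The individual-differences analysis correlates two change scores that are
each built from eight noisy proportions, so even a true anodal/cathodal
effect correlation of -.45 is observed shrunken. This Monte-Carlo curve
shows the expected recovered partial correlation as the per-block trial
budget grows; at the study's actual ~130 short-lag trials the attenuation
is substantial. Writes results/attenuation.csv.
"""

from pathlib import Path

from blinkrep import SimConfig, attenuation_curve

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimConfig(seed=40)
    curve = attenuation_curve(cfg, [33, 65, 130, 260, 520, 1040], n_reps=300, seed=40)
    curve.to_csv(OUT / "attenuation.csv", index=False)
    print(f"true effect correlation: {cfg.rho_true}")
    print(curve.to_string(index=False,
                          formatters={"mean_r": "{:.3f}".format, "sd_r": "{:.3f}".format}))
    at_design = curve.set_index("trials_short").loc[130, "mean_r"]
    print(
        f"\nat the study's ~130 short-lag trials per block the expected "
        f"recovered correlation is {at_design:.2f} — roughly "
        f"{abs(at_design / cfg.rho_true):.0%} of the true latent correlation."
    )


if __name__ == "__main__":
    main()
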