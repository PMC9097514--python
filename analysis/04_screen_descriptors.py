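#!/usr/bin/env python
"""Descriptor-property screening demonstrated on a synthetic drug panel.

The measured per-drug nanogel properties behind the original screen are
not distributed in numeric form, so this driver generates a SYNTHETIC
six-drug beta-blocker-like panel with known planted relationships —
a negative linear size~XLogP trend, an exponential PDI~bpol trend, and
constant nAcid/nBase columns — and screens all fifteen descriptors
against size, PDI and zeta potential under all four functional forms.
"""

import json
from pathlib import Path

from formurs import (PlantedRelation, SyntheticTruth, screen_all,
                     simulate_descriptor_panel)
from formurs.descriptor_screen import DEFAULT_PANEL

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 17


def main() -> None:
    truth = SyntheticTruth(
        coefficients={"1": 0.0}, sigma=0.0, seed=SEED,
        descriptor_relations=(
            PlantedRelation("XLogP", "size", "linear", (120.0, -7.0), 6.0),
            PlantedRelation("bpol", "PDI", "exp", (0.12, 0.22), 0.01),
            PlantedRelation("apol", "ZP", "quadratic", (18.0, 4.0, -0.35), 1.0),
        ))
    filler = [d for d in DEFAULT_PANEL
              if d not in ("XLogP", "bpol", "apol", "nAcid", "nBase")]
    desc, props = simulate_descriptor_panel(
        truth, n_drugs=6, noise_descriptors=filler,
        zero_variance=("nAcid", "nBase"))

    result = screen_all(desc, props)
    print("signed R2 grid, linear form:")
    print(result.render("linear"))
    strong = result.strong()
    print(f"\n{len(strong)} cells pass |R2| > 0.7 with p < 0.05:")
    for _, row in strong.iterrows():
        print(f"  {row.descriptor:>12} ~ {row.property:<4} [{row.form}] "
              f"signed R2 = {row.r2_signed:+.3f}, p = {row.p:.4f}"
              + ("  (quadratic vertex outside data: overfit risk)"
                 if row.overfit_risk else ""))
    print("\nThe planted pairs surface as the strong cells; the constant "
          "acid/base-count columns screen to exactly 0, and noise "
          "descriptors stay below the moderate threshold almost everywhere.")

    result.grid.to_csv(OUT / "screen_synthetic.csv", index=False)
    (OUT / "screen_synthetic_truth.json").write_text(json.dumps({
        "seed": SEED,
        "planted": [{"descriptor": r.descriptor, "property": r.property,
                     "form": r.form, "coefficients": r.coefficients,
                     "sigma": r.sigma} for r in truth.descriptor_relations],
    }, indent=1))
    print(f"wrote {OUT}/screen_synthetic.csv (+ truth sidecar)")


if __name__ == "__main__":
    main()
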