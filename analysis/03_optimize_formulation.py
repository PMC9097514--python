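#!/usr/bin/env python
"""Find the optimal formulation and the 100 / 200 nm target settings.

Runs Derringer-Suich multi-response optimization (minimize size and
PDI, maximize zeta potential and encapsulation efficiency, bounds at
the observed training ranges) over the design cube, then solves the two
inverse problems: settings whose predicted size hits 100 and 200 nm
while minimizing predicted PDI.
"""

import json
from pathlib import Path

from formurs import (ModelSpec, REPORTED_TERM_SETS, fit_ols, inverse_target,
                     load_training_design, optimize_mro)
from formurs.workflow import default_goals

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    train = load_training_design()
    models = {resp: fit_ols(train, ModelSpec.from_strings(resp, terms))
              for resp, terms in REPORTED_TERM_SETS.items()}

    mro = optimize_mro(models, default_goals(train), grid=41)
    raw = mro.argmax_raw
    print(f"Optimum: CC = {raw['CC']:.3f} % w/v, C/T = {raw['CT']:.2f}, "
          f"C/P = {raw['CP']:.3f}  (overall D = {mro.overall_D:.4f})")
    for resp, (pred, d) in mro.per_response.items():
        shown = pred * 100 if resp == "EE" else pred
        unit = {"size": "nm", "ZP": "mV", "EE": "%"}.get(resp, "")
        print(f"  {resp:>4}: predicted {shown:8.3f} {unit:2}  d = {d:.3f}")
    print("The optimum sits on the low-chitosan / low-TPP-ratio / "
          "high-drug-ratio edge of the cube: small particles dominate the "
          "trade-off.")

    targets = {}
    for target_nm in (100.0, 200.0):
        res = inverse_target(models, ("size", target_nm), ("PDI", "minimize"),
                             grid=41)
        targets[str(int(target_nm))] = {
            "settings_raw": res.settings_raw,
            "predicted_size": res.predicted_primary,
            "predicted_PDI": res.predicted_secondary,
            "feasible": res.feasible,
        }
        s = res.settings_raw
        print(f"\n{target_nm:.0f} nm target -> CC {s['CC']:.3f}, "
              f"C/T {s['CT']:.2f}, C/P {s['CP']:.3f}: predicted size "
              f"{res.predicted_primary:.1f} nm, PDI {res.predicted_secondary:.3f}")

    payload = {"optimum": {"settings_raw": mro.argmax_raw,
                           "settings_coded": mro.argmax_coded,
                           "overall_D": mro.overall_D,
                           "per_response": mro.per_response},
               "size_targets": targets}
    (OUT / "optimum.json").write_text(json.dumps(payload, indent=1))
    print(f"\nwrote {OUT}/optimum.json")


if __name__ == "__main__":
    main()
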