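#!/usr/bin/env python
"""Binding-affinity and ATPase-rate analysis on simulated assay data.

Two scenarios mirror the assay design this package analyses:

* anisotropy titrations of the loader against labeled primer-template
  DNA in the presence of wild-type clamp (Kd 100 nM) versus a
  charge-quadruple-mutant clamp (5x weaker), each fit to the one-site
  hyperbola Y = Bmax X / (Kd + X); and
* coupled-assay NADH-depletion timecourses across the DNA length
  series, normalized to the wild-type clamp + DNA-30 condition.  The
  mutant-clamp traces are generated at the clamp-free rate for long
  constructs and approach wild-type for the shortest construct — the
  simulated analog of DNA-length-dependent loss of stimulation.

Writes ``results/binding_fits.csv`` and ``results/relative_rates.csv``.
"""

from pathlib import Path

import pandas as pd

from clampdna.binding_kinetics import (
    compare_fits,
    fit_one_site,
    rate_from_timecourse,
    relative_rates,
)
from clampdna.synthetic_data import (
    TimecourseSpec,
    TitrationSpec,
    simulate_atpase_timecourse,
    simulate_titration,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

# generative slopes (AU/s): wild-type clamp fully stimulates at every
# length; the mutant clamp tracks the clamp-free rate for constructs
# long enough to reach into the ring and recovers for short ones
RATE_SCENARIO = {
    "wt+DNA-30": -2.0e-4, "wt+DNA-25": -1.9e-4, "wt+DNA-20": -2.0e-4,
    "wt+DNA-15": -1.9e-4, "wt+DNA-13": -2.0e-4,
    "mut+DNA-30": -5.0e-5, "mut+DNA-25": -5.0e-5, "mut+DNA-20": -5.5e-5,
    "mut+DNA-15": -1.2e-4, "mut+DNA-13": -1.9e-4,
    "noPCNA+DNA-30": -5.0e-5,
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    wt_ds = simulate_titration(TitrationSpec(kd=100.0, seed=11,
                                             label="wild-type clamp"))
    mut_ds = simulate_titration(TitrationSpec(
        kd=500.0, seed=12, label="quadruple mutant",
        x=(25, 50, 100, 200, 400, 800, 1600, 3200)))
    fits = [fit_one_site(wt_ds), fit_one_site(mut_ds)]
    fit_table = pd.DataFrame([
        {"condition": f.label, "Kd_nM": round(f.kd, 2),
         "Kd_se_nM": round(f.kd_se, 2), "Bmax": round(f.bmax, 4),
         "Bmax_se": round(f.bmax_se, 4), "n_points": f.n}
        for f in fits])
    fit_table.to_csv(RESULTS / "binding_fits.csv", index=False)
    fc = compare_fits(fits[0], fits[1])
    print(fit_table.to_string(index=False))
    print(f"mutant clamp binds DNA {fc.ratio:.2f} ± {fc.se:.2f} times "
          f"more weakly than wild type (generated at 5x)\n")

    measurements = [
        rate_from_timecourse(simulate_atpase_timecourse(
            TimecourseSpec(slope=s, seed=100 + i, label=label)))
        for i, (label, s) in enumerate(RATE_SCENARIO.items())]
    table = relative_rates(measurements, "wt+DNA-30")
    table["relative_rate"] = table["relative_rate"].round(4)
    table.to_csv(RESULTS / "relative_rates.csv", index=False)
    print(table.to_string(index=False))
    rel = table.set_index("condition")["relative_rate"]
    print(f"\nmutant relative rate with DNA-30 ({rel['mut+DNA-30']:.2f}) "
          f"matches the clamp-free level ({rel['noPCNA+DNA-30']:.2f}); "
          f"with DNA-13 it recovers to {rel['mut+DNA-13']:.2f}")


if __name__ == "__main__":
    main()
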