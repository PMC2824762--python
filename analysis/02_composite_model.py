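#!/usr/bin/env python
"""Assemble the composite loader-clamp-DNA model from a dismantled
fixture and score the reassembly against the retained ground truth.

The fixture generator builds one loader+clamp+DNA assembly, then emits
the loader-DNA and loader-clamp partial complexes in different frames
related by hidden random rigid transforms.  The composite build must
recover the DNA placement from the shared anchor (B) subunit alone.
Writes ``results/composite_model.csv`` and the composite coordinates
plus provenance log under ``scratch/``.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from clampdna.clamp_pipeline import build_composite_model, replay_composite
from clampdna.geometry import fit_helical_axis, ring_axis, tilt_angle
from clampdna.structio import select, write_structure
from clampdna.synthetic_data import make_composite_fixture

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    fx = make_composite_fixture(seed=3, tilt=12.0, dna_bp=40)
    model = build_composite_model(fx.loader_dna_complex,
                                  fx.loader_clamp_complex, ("V", "V"),
                                  extension_length=8)
    truth = fx.true_dna_in_clamp_frame
    placement_err = float(np.abs(
        model.duplex.bp_centers[:truth.n_bp] - truth.bp_centers).max())

    meta = fx.loader_clamp_complex.metadata
    clamp = select(fx.loader_clamp_complex,
                   "chain " + ",".join(meta["clamp_chains"]))
    ax = ring_axis(clamp, meta["n_fold"])
    tilt = tilt_angle(fit_helical_axis(model.duplex.bp_centers), ax)

    again = replay_composite(model.log, fx.loader_dna_complex,
                             fx.loader_clamp_complex)
    replay_ok = np.array_equal(
        model.duplex.atoms.coords(primary_only=False),
        again.duplex.atoms.coords(primary_only=False))

    spacing = np.linalg.norm(np.diff(model.duplex.bp_centers, axis=0), axis=1)
    row = {
        "anchor_rmsd_A": round(model.anchor_rmsd, 9),
        "dna_placement_error_A": placement_err,
        "true_tilt_deg": fx.true_tilt,
        "recovered_tilt_deg": round(tilt, 6),
        "extension_bp": 8,
        "seam_spacing_min_A": round(float(spacing.min()), 4),
        "seam_spacing_max_A": round(float(spacing.max()), 4),
        "replay_bit_identical": replay_ok,
        "clash_warnings": len(model.clash_warnings),
    }
    pd.DataFrame([row]).to_csv(RESULTS / "composite_model.csv", index=False)
    write_structure(model.structure(), SCRATCH / "composite_model.pdb")
    (SCRATCH / "composite_model.log.json").write_text(
        json.dumps(model.log, indent=2))

    print(f"anchor superposition rmsd: {model.anchor_rmsd:.2e} Å")
    print(f"DNA placement error vs ground truth: {placement_err:.2e} Å")
    print(f"tilt through the clamp: {tilt:.3f}° (constructed "
          f"{fx.true_tilt}°)")
    print(f"extension seam spacing: {spacing.min():.3f}-{spacing.max():.3f} Å "
          f"per bp (ideal rise {model.duplex.rise} Å)")
    print(f"provenance replay bit-identical: {replay_ok}")


if __name__ == "__main__":
    main()
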