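#!/usr/bin/env python
"""Validation battery against locally cached deposited coordinates.

Run ``python scripts/fetch_structures.py`` first (network required);
then this script checks, entirely offline, the quantities the package
should reproduce on the real structures:

* 3K4X composition: 6761 non-hydrogen, non-solvent atoms in total and
  407 nucleic-acid atoms;
* 3K4X DNA tilt vs the clamp ring axis ~ 40 deg (both axis methods
  reported; tolerance +-3 deg given the unstated measurement
  convention);
* 1PLQ / 3K4X clamp ring-axis cross-method agreement within 3 deg;
* beta clamp-DNA (3BEP) duplex tilt ~ 22 deg (plane method over the
  dimer; the six-fold domain-level symmetry needs a domain map, so the
  plane normal is the default here);
* composite model from the gamma-complex-DNA (3GLF) and RFC-PCNA
  (1SXJ) structures anchored on their B subunits, with the duplex
  extended through the clamp: tilt vs the PCNA ring axis ~ 26 deg less
  than the 3K4X tilt, minimum spanning duplex ~ 25 bp, and the 20/15 bp
  truncations classifying partial/opening.

Any check whose inputs are missing is reported as SKIPPED, and a
divergent number is printed, not hidden.

Usage::

    python scripts/validate_deposited.py [--dir structures/]
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from clampdna.clamp_pipeline import (
    build_composite_model,
    duplex_from_structure,
    find_contacts,
)
from clampdna.geometry import (
    axial_span,
    fit_helical_axis,
    min_bp_to_span,
    ring_axis,
    tilt_angle,
)
from clampdna.structio import count_atoms, read_structure, select


def check(name: str, value, expected: str) -> None:
    print(f"  {name}: {value}   (expected {expected})")


def validate_3k4x(path: Path) -> None:
    s = read_structure(path)
    print(f"[3K4X] {path}")
    check("non-H, non-solvent atoms", count_atoms(s), "6761")
    dna = select(s, "kind dna")
    check("nucleic-acid atoms", count_atoms(dna), "407")
    clamp = select(s, "kind protein")
    duplex = duplex_from_structure(dna)
    for method in ("symmetry", "plane"):
        try:
            ax = ring_axis(clamp, n_fold=3, method=method)
            tilt = tilt_angle(fit_helical_axis(duplex.bp_centers), ax)
            check(f"DNA tilt ({method} axis)", f"{tilt:.1f} deg", "~40 deg")
        except ValueError as exc:
            print(f"  DNA tilt ({method}): FAILED ({exc})")
    table = find_contacts(clamp, dna, cutoff=4.0, dna_atom_filter="phosphate")
    his190 = table[(table.residue_number == 190)
                   & (table.residue_name == "HIS")]
    asn_loop = table[table.residue_number.isin([83, 84])
                     & (table.residue_name == "ASN")]
    basics = table[table.residue_number.isin([13, 14, 146, 149])]
    check("His 190 phosphate contacts", len(his190), ">= 1")
    check("Asn 83/84 loop contacts", len(asn_loop), ">= 1")
    check("K13/R14/K146/R149 contacts", len(basics), ">= 1")


def validate_1plq(path: Path) -> None:
    s = read_structure(path)
    print(f"[1PLQ] {path}")
    clamp = select(s, "kind protein")
    a = ring_axis(clamp, 3, method="symmetry")
    b = ring_axis(clamp, 3, method="plane")
    check("axis method agreement", f"{tilt_angle(a.direction, b.direction):.2f} deg",
          "< 3 deg")


def validate_beta_clamp(path: Path) -> None:
    s = read_structure(path)
    print(f"[beta clamp-DNA] {path}")
    clamp = select(s, "kind protein")
    dna = select(s, "kind dna")
    try:
        duplex = duplex_from_structure(dna)
        centers = duplex.bp_centers
    except ValueError:
        # modeled strands of unequal length: fall back on C1' cloud PCA
        centers = dna.coords(atom_name="C1'")
    ax = ring_axis(clamp, n_fold=2, method="plane")
    tilt = tilt_angle(fit_helical_axis(centers), ax)
    check("DNA tilt (plane axis)", f"{tilt:.1f} deg", "~22 deg")


def validate_composite(gamma_path: Path, rfc_path: Path,
                       tilt_3k4x: float | None) -> None:
    gamma = read_structure(gamma_path)
    rfc = read_structure(rfc_path)
    print(f"[composite] {gamma_path} + {rfc_path}")
    # B subunits: second position in the loader's A-E spiral; chain ids
    # follow each deposition's labeling and may need overriding
    model = build_composite_model(gamma, rfc, ("B", "B"),
                                  extension_length=30)
    clamp = select(rfc, "kind protein")
    pcna_chains = [cid for cid in clamp.chains][-3:]   # PCNA trails RFC
    pcna = select(rfc, "chain " + ",".join(pcna_chains))
    ax = ring_axis(pcna, 3, method="plane")
    tilt = tilt_angle(fit_helical_axis(model.duplex.bp_centers), ax)
    check("composite duplex tilt", f"{tilt:.1f} deg", "~14 deg (40 - 26)")
    if tilt_3k4x is not None:
        check("3K4X tilt minus composite tilt",
              f"{tilt_3k4x - tilt:.1f} deg", "~26 deg")
    search = min_bp_to_span(model.duplex, ax, pcna)
    check("minimum spanning duplex", search.min_bp, "~25 bp")
    for n_bp, expected in ((20, "partial"), (15, "opening")):
        rep = axial_span(model.duplex.bp_centers[:n_bp], ax, pcna)
        check(f"{n_bp} bp classification", rep.classification, expected)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dir", type=Path, default=Path("structures"))
    args = parser.parse_args()

    def find(acc: str) -> Path | None:
        for suffix in (".cif", ".pdb"):
            p = args.dir / f"{acc}{suffix}"
            if p.exists():
                return p
        print(f"[{acc}] SKIPPED (no {acc}.cif/.pdb under {args.dir})")
        return None

    p3k4x = find("3K4X")
    tilt_3k4x = None
    if p3k4x:
        validate_3k4x(p3k4x)
        s = read_structure(p3k4x)
        try:
            duplex = duplex_from_structure(select(s, "kind dna"))
            ax = ring_axis(select(s, "kind protein"), 3, method="plane")
            tilt_3k4x = tilt_angle(fit_helical_axis(duplex.bp_centers), ax)
        except ValueError:
            pass
    if (p := find("1PLQ")):
        validate_1plq(p)
    if (p := find("3BEP")):
        validate_beta_clamp(p)
    gamma, rfc = find("3GLF"), find("1SXJ")
    if gamma and rfc:
        try:
            validate_composite(gamma, rfc, tilt_3k4x)
        except Exception as exc:     # chain labeling varies by deposition
            print(f"  composite build FAILED: {exc}")
            print("  (override anchor chains per the depositions' labeling)")


if __name__ == "__main__":
    main()
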