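"""Ideal B-form DNA duplex generation.

Builds heavy-atom coordinates for double-stranded B-DNA from sequence,
on a straight helical axis along +z with base pair 1 at z = 0.  The
internal base/sugar geometry comes from a single embedded idealized
heavy-atom template per deoxynucleotide (no hydrogens): atom placement
is schematic but dimensionally realistic (phosphate backbone at ~9.6 Å
radius, paired C1'-C1' separation 10.4 Å with the pair midpoint exactly
on the axis).  Downstream consumers use only base-pair centers, backbone
atom positions and heavy-atom counts, none of which depend on fine
base-geometry detail; sequence-dependent bending, propeller twist and
groove asymmetry are deliberately not modeled.

Default helical parameters are canonical fiber B-form values:
rise 3.38 Å/bp, twist 36.0°/bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structio import Atom, Residue, Structure

__all__ = [
    "DuplexModel",
    "Pairing",
    "AnnealError",
    "reverse_complement",
    "anneal",
    "build_bform_duplex",
    "bp_centers",
    "HEAVY_ATOM_COUNT",
    "sequence_from_fasta",
]

B_FORM_RISE = 3.38       # Å per base pair
B_FORM_TWIST = 36.0      # degrees per base pair

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class AnnealError(ValueError):
    """Two strands have no unambiguous Watson-Crick register."""


def _validate_sequence(seq: str, role: str = "sequence") -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in _COMPLEMENT:
            raise ValueError(f"{role}: invalid character {ch!r} at position {i + 1}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a 5'->3' sequence (returned 5'->3')."""
    seq = _validate_sequence(seq)
    return "".join(_COMPLEMENT[ch] for ch in reversed(seq))


# ---------------------------------------------------------------------------
# annealing
# ---------------------------------------------------------------------------

@dataclass
class Pairing:
    """A contiguous antiparallel Watson-Crick register between two strands.

    ``pairs`` holds 0-based (strand1 index, strand2 index) tuples ordered
    5'->3' along strand 1; strand-2 indices therefore decrease.
    ``overhangs`` lists the unpaired termini as
    ``{"strand": 1|2, "end": "5'"|"3'", "length": n}``.
    """

    seq1: str
    seq2: str
    pairs: list[tuple[int, int]]
    overhangs: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def duplex_seq1(self) -> str:
        return "".join(self.seq1[i] for i, _ in self.pairs)

    @property
    def duplex_seq2(self) -> str:
        """Paired portion of strand 2, written 5'->3' along strand 2."""
        return "".join(self.seq2[j] for _, j in reversed(self.pairs))


def anneal(seq1: str, seq2: str, min_register: int = 4) -> Pairing:
    """Find the maximal contiguous antiparallel Watson-Crick register.

    Slides strand 1 against the reverse complement of strand 2 and keeps
    the longest contiguous perfectly complementary run; unpaired termini
    are reported as 5'/3' overhangs.  A run shorter than ``min_register``
    raises :class:`AnnealError` (ambiguous construct).
    """
    seq1 = _validate_sequence(seq1, "strand 1")
    seq2 = _validate_sequence(seq2, "strand 2")
    rc2 = reverse_complement(seq2)
    n1, n2 = len(seq1), len(seq2)

    best_len, best_start1, best_off = 0, 0, 0
    for off in range(-(n1 - 1), n2):
        run = 0
        for k1 in range(n1):
            k2 = k1 + off
            if 0 <= k2 < n2 and seq1[k1] == rc2[k2]:
                run += 1
                if run > best_len:
                    best_len, best_start1, best_off = run, k1 - run + 1, off
            else:
                run = 0
    if best_len < min_register:
        raise AnnealError(
            f"no perfect antiparallel register of length >= {min_register} "
            f"between the two strands (best run: {best_len})")

    pairs = []
    for k in range(best_len):
        i = best_start1 + k
        j = n2 - 1 - (i + best_off)   # rc2 index back to seq2 index
        pairs.append((i, j))

    i_min, j_max = pairs[0]
    i_max, j_min = pairs[-1]
    overhangs = []
    for strand, end, length in (
        (1, "5'", i_min),
        (1, "3'", n1 - 1 - i_max),
        (2, "5'", j_min),
        (2, "3'", n2 - 1 - j_max),
    ):
        if length > 0:
            overhangs.append({"strand": strand, "end": end, "length": length})
    return Pairing(seq1, seq2, pairs, overhangs)


# ---------------------------------------------------------------------------
# idealized heavy-atom nucleotide templates
# ---------------------------------------------------------------------------

# Local base-pair frame: helical axis = z, base pair plane ~ z = 0,
# strand-1 C1' at (0, 5.2, 0).  Strand 2 is generated from the template
# of the complementary base by the pair dyad (x, y, z) -> (x, -y, -z),
# which puts the paired C1' at (0, -5.2, 0) and the C1'-C1' midpoint
# exactly on the axis.
_SUGAR = [
    ("C1'", (0.00, 5.20, 0.00)),
    ("O4'", (-1.05, 5.95, 0.35)),
    ("C4'", (-0.75, 7.30, 0.10)),
    ("C3'", (0.65, 7.55, -0.30)),
    ("C2'", (1.25, 6.20, -0.45)),
    ("O3'", (0.85, 8.45, 0.70)),
    ("C5'", (-1.75, 8.20, 0.75)),
]
_PHOSPHATE = [
    ("O5'", (-1.55, 8.60, 2.10)),
    ("P", (-1.25, 9.55, 3.20)),
    ("OP1", (-2.45, 10.15, 3.75)),
    ("OP2", (-0.30, 10.45, 2.60)),
]
# O5' belongs to the residue whether or not the terminal phosphate is
# present; only P/OP1/OP2 are subject to the 5'-phosphate policy.
_O5_PRIME = [_PHOSPHATE[0]]
_P_GROUP = _PHOSPHATE[1:]

_PURINE_RING = [
    ("N9", (0.45, 3.95, 0.10)),
    ("C8", (1.55, 3.25, 0.10)),
    ("N7", (1.35, 1.95, 0.10)),
    ("C5", (0.05, 1.85, 0.10)),
    ("C4", (-0.55, 3.05, 0.10)),
    ("N3", (-1.85, 3.20, 0.10)),
    ("C2", (-2.50, 2.10, 0.10)),
    ("N1", (-2.05, 0.85, 0.10)),
    ("C6", (-0.75, 0.65, 0.10)),
]
_PYRIMIDINE_RING = [
    ("N1", (0.45, 3.95, 0.10)),
    ("C2", (-0.25, 2.80, 0.10)),
    ("O2", (-1.50, 2.85, 0.10)),
    ("N3", (0.40, 1.65, 0.10)),
    ("C4", (1.75, 1.65, 0.10)),
    ("C5", (2.45, 2.85, 0.10)),
    ("C6", (1.80, 3.95, 0.10)),
]

_BASE_ATOMS = {
    "A": _PURINE_RING + [("N6", (-0.30, -0.60, 0.10))],
    "G": _PURINE_RING + [("O6", (-0.30, -0.60, 0.10)),
                         ("N2", (-3.80, 2.20, 0.10))],
    "C": _PYRIMIDINE_RING + [("N4", (2.40, 0.50, 0.10))],
    "T": _PYRIMIDINE_RING + [("O4", (2.40, 0.55, 0.10)),
                             ("C7", (3.95, 2.90, 0.10))],
}

#: Heavy atoms per deoxynucleotide including one 5'-phosphate group.
HEAVY_ATOM_COUNT = {base: len(_SUGAR) + len(_PHOSPHATE) + len(_BASE_ATOMS[base])
                    for base in "ACGT"}  # A 21, C 19, G 22, T 20
N_PHOSPHATE_GROUP_ATOMS = len(_P_GROUP)  # P, OP1, OP2

_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


def _element_of(atom_name: str) -> str:
    return atom_name[0]  # heavy atoms only: C/N/O/P


def _nucleotide_template(base: str, with_phosphate: bool) -> list[tuple[str, np.ndarray]]:
    atoms = list(_SUGAR) + list(_O5_PRIME)
    if with_phosphate:
        atoms += list(_P_GROUP)
    atoms += _BASE_ATOMS[base]
    return [(name, np.array(xyz, dtype=float)) for name, xyz in atoms]


# ---------------------------------------------------------------------------
# duplex building
# ---------------------------------------------------------------------------

@dataclass
class DuplexModel:
    """A built or extracted double-stranded DNA model.

    ``pairing`` indexes into the full input strand sequences (0-based);
    ``bp_centers`` (midpoints of paired C1' atoms) are ordered along
    strand 1, 5'->3', index 0 = first pair.
    """

    strand1_seq: str
    strand2_seq: str
    pairing: list[tuple[int, int]]
    atoms: Structure
    bp_centers: np.ndarray
    rise: float = B_FORM_RISE
    twist: float = B_FORM_TWIST

    def __post_init__(self) -> None:
        self.bp_centers = np.asarray(self.bp_centers, dtype=float)
        if len(self.bp_centers) != len(self.pairing):
            raise ValueError("one bp center per pair required")
        for (i, j), (i2, j2) in zip(self.pairing, self.pairing[1:]):
            if not (i2 == i + 1 and j2 == j - 1):
                raise ValueError("pairing must be contiguous and antiparallel")
        for i, j in self.pairing:
            b1, b2 = self.strand1_seq[i], self.strand2_seq[j]
            if _COMPLEMENT[b1] != b2:
                raise ValueError(f"non-Watson-Crick pair {b1}.{b2} at {i},{j}")

    @property
    def n_bp(self) -> int:
        return len(self.pairing)

    @property
    def duplex_seq1(self) -> str:
        return "".join(self.strand1_seq[i] for i, _ in self.pairing)

    def transformed(self, transform) -> "DuplexModel":
        """A copy with atoms and bp centers mapped by a rigid transform
        (any object with an ``apply(points)`` method)."""
        coords = self.atoms.coords(primary_only=False)
        return DuplexModel(
            self.strand1_seq, self.strand2_seq, list(self.pairing),
            self.atoms.with_coords(transform.apply(coords)),
            transform.apply(self.bp_centers), self.rise, self.twist)


def _rot_z(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

_DYAD = np.diag([1.0, -1.0, -1.0])  # base-pair dyad about the local x axis


def build_bform_duplex(seq1: str,
                       seq2: str | None = None,
                       rise: float = B_FORM_RISE,
                       twist: float = B_FORM_TWIST,
                       phosphate5_strand1: bool = False,
                       phosphate5_strand2: bool = False,
                       structure_id: str = "duplex") -> DuplexModel:
    """Build an ideal straight B-form duplex with axis along +z.

    ``seq2`` defaults to the full reverse complement of ``seq1``; when
    given, the two strands are annealed first and only the paired region
    receives coordinates (overhang nucleotides are left unbuilt).  The
    5'-terminal phosphate group (P/OP1/OP2) of each strand's first
    *modeled* nucleotide is included only when the corresponding policy
    flag is set; the default is a 5'-OH terminus.
    """
    seq1 = _validate_sequence(seq1, "strand 1")
    if rise <= 0:
        raise ValueError(f"non-physical rise {rise} (must be > 0)")
    if abs(twist) > 60:
        raise ValueError(f"non-physical twist {twist} (|twist| must be <= 60 deg)")
    if seq2 is None:
        seq2 = reverse_complement(seq1)
    pairing = anneal(seq1, seq2, min_register=min(4, len(seq1)))
    n = len(pairing)

    chain1: list[Residue] = []
    chain2: list[Residue] = []
    centers = np.zeros((n, 3))
    serial = 0

    def make_residue(chain_id: str, number: int, base: str,
                     frame_rot: np.ndarray, z_shift: float,
                     with_phosphate: bool, dyad: bool) -> Residue:
        nonlocal serial
        atoms = []
        for name, local in _nucleotide_template(base, with_phosphate):
            xyz = (_DYAD @ local) if dyad else local
            xyz = frame_rot @ xyz + np.array([0.0, 0.0, z_shift])
            serial += 1
            atoms.append(Atom(serial=serial, name=name,
                              element=_element_of(name), coord=xyz))
        return Residue(chain_id, number, _RESNAME[base], atoms)

    for k, (i, j) in enumerate(pairing.pairs):
        rot = _rot_z(k * twist)
        z = k * rise
        centers[k] = (0.0, 0.0, z)
        with_p1 = phosphate5_strand1 or k > 0
        chain1.append(make_residue("1", i + 1, seq1[i], rot, z, with_p1, False))
        # strand 2: 5'-terminal modeled nucleotide is the *last* pair
        with_p2 = phosphate5_strand2 or k < n - 1
        chain2.append(make_residue("2", j + 1, seq2[j], rot, z, with_p2, True))

    # order strand 2 residues 5'->3' along strand 2
    chain2.reverse()

    structure = Structure(id=structure_id,
                          chains={"1": chain1, "2": chain2},
                          metadata={"rise": rise, "twist": twist})
    return DuplexModel(seq1, seq2, list(pairing.pairs), structure, centers,
                       rise=rise, twist=twist)


def bp_centers(d: DuplexModel) -> np.ndarray:
    """Recompute base-pair centers as midpoints of paired C1' atoms.

    Ordered 5'->3' along strand 1.  Raises ``KeyError`` naming the
    residue if a C1' atom is missing.
    """
    if d.n_bp < 1:
        raise ValueError("duplex has no base pairs")
    res1 = {r.number: r for r in d.atoms.chains["1"]}
    res2 = {r.number: r for r in d.atoms.chains["2"]}
    out = np.zeros((d.n_bp, 3))
    for k, (i, j) in enumerate(d.pairing):
        c1 = res1[i + 1].atom("C1'").coord
        c2 = res2[j + 1].atom("C1'").coord
        out[k] = 0.5 * (c1 + c2)
    return out


def sequence_from_fasta(path: str | Path) -> str:
    """First record of a FASTA file as an uppercase sequence string."""
    from Bio import SeqIO
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()
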