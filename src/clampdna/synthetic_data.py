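"""Synthetic fixtures for clamp/DNA geometry and assay statistics.

Every generator is a pure function of its spec (seed included), so
fixtures are bitwise reproducible and each geometric generator has a
closed-form ground truth that the corresponding measurement operation
must recover — the closure between construction parameter and measured
value is the reason this module exists.

The geometric stand-ins are deliberately schematic: ring clamps are
Calpha-only pseudo-subunits related by exact 360/n rotations (the
ring-axis and span code consume Calpha exclusively), and the pseudo
"loader" is a set of Calpha blobs arranged against the clamp's proximal
face.  Real folds, crystal packing and density are out of scope.

Default study conditions mirror the assay design this package analyses:
titrations at a wild-type dissociation constant of 100 nM with ~5%
amplitude noise, and linear NADH-depletion timecourses sampled over
0-600 s and fit over the 100-500 s window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dna_builder
from .binding_kinetics import Timecourse, TitrationDataset
from .dna_builder import DuplexModel, build_bform_duplex
from .geometry import RigidTransform, ring_axis, _face_planes
from .structio import Atom, Residue, Structure

__all__ = [
    "SyntheticClampSpec",
    "TitrationSpec",
    "TimecourseSpec",
    "make_synthetic_clamp",
    "make_tilted_duplex",
    "make_composite_fixture",
    "simulate_titration",
    "simulate_atpase_timecourse",
    "PSEUDO_SEQUENCE",
]

#: Residue names cycled along each pseudo-subunit; Lys/Arg sit at known
#: positions so the basic-residue inventory can be exercised synthetically.
PSEUDO_SEQUENCE = [
    "GLY", "ALA", "LYS", "SER", "ARG", "LEU", "ASP", "LYS", "VAL", "THR",
    "ARG", "GLU", "ILE", "ASN", "LYS", "PHE", "GLN", "ARG", "MET", "HIS",
]


@dataclass(frozen=True)
class SyntheticClampSpec:
    """An idealized n-fold ring clamp of Calpha pseudo-subunits."""

    n_fold: int = 3
    radius: float = 32.0          # Å, outer radius of the subunit annulus
    thickness: float = 27.0       # Å, axial depth of the ring
    atoms_per_subunit: int = 60
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fold < 2:
            raise ValueError("n_fold must be >= 2")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")


def _rotation_to(axis: np.ndarray) -> RigidTransform:
    """Deterministic rotation taking +z to ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        return RigidTransform(R, np.zeros(3))
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    return RigidTransform(R, np.zeros(3))


def make_synthetic_clamp(spec: SyntheticClampSpec) -> Structure:
    """Generate an exactly n-fold symmetric Calpha-only ring.

    One seeded pseudo-subunit (atoms in an annular wedge, radial
    distance in [0.6, 1.0] x radius, so the ring is hollow) is copied by
    exact 360/n rotations about the spec axis.  Chains are labeled
    A, B, C, ... with residues numbered from 1, one Calpha each.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.atoms_per_subunit
    wedge = 2 * np.pi / spec.n_fold
    radial = rng.uniform(0.6 * spec.radius, spec.radius, m)
    phi = rng.uniform(-0.45 * wedge, 0.45 * wedge, m)
    z = rng.uniform(-spec.thickness / 2, spec.thickness / 2, m)
    subunit = np.column_stack([radial * np.cos(phi), radial * np.sin(phi), z])

    frame = _rotation_to(np.array(spec.axis))
    structure = Structure(id="synthetic_clamp",
                          metadata={"spec": spec, "n_fold": spec.n_fold})
    serial = 0
    for k in range(spec.n_fold):
        theta = 2 * np.pi * k / spec.n_fold
        c, s = np.cos(theta), np.sin(theta)
        Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        coords = frame.apply(subunit @ Rz.T)
        residues = []
        for i, xyz in enumerate(coords):
            serial += 1
            atom = Atom(serial=serial, name="CA", element="C", coord=xyz)
            residues.append(Residue(chain_id="", number=i + 1,
                                    name=PSEUDO_SEQUENCE[i % len(PSEUDO_SEQUENCE)],
                                    atoms=[atom]))
        structure.add_chain(chr(ord("A") + k), residues)
    return structure


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), length))


def make_tilted_duplex(ring: Structure, tilt: float, offset: float,
                       length: int, seed: int = 0,
                       rise: float = dna_builder.B_FORM_RISE,
                       twist: float = dna_builder.B_FORM_TWIST,
                       sequence: str | None = None,
                       entry_axial: float | None = None) -> DuplexModel:
    """Place an ideal duplex through a ring at a known tilt.

    The duplex axis makes ``tilt`` degrees with the ring axis (tilting in
    a deterministic perpendicular direction) and is displaced ``offset``
    Å from the ring center, entering at the proximal face plane (bp 1 at
    the plane, or at ``entry_axial`` Å relative to it when given).
    """
    if abs(tilt) > 60:
        raise ValueError(f"|tilt| must be <= 60 deg, got {tilt}")
    n_fold = ring.metadata.get("n_fold", len(ring.chains))
    axis = ring_axis(ring, n_fold=n_fold, method="symmetry")
    ca = ring.coords(atom_name="CA")
    hole_radius = float(np.min(np.linalg.norm(
        ca - axis.origin - np.outer(axis.axial_coordinates(ca), axis.direction),
        axis=1)))
    if abs(offset) >= hole_radius:
        raise ValueError(f"offset {offset} Å misses the ring aperture "
                         f"(hole radius ~{hole_radius:.1f} Å)")

    rng = np.random.default_rng(seed)
    seq = sequence if sequence is not None else _random_sequence(rng, length)
    if len(seq) != length:
        raise ValueError("sequence length does not match requested bp count")
    duplex = build_bform_duplex(seq, rise=rise, twist=twist)

    # deterministic in-ring frame: e1 perpendicular to the ring axis
    d = axis.direction
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    target_dir = np.cos(np.deg2rad(tilt)) * d + np.sin(np.deg2rad(tilt)) * e1

    s_prox, _ = _face_planes(ring, axis, 5.0, 95.0)
    entry = s_prox if entry_axial is None else s_prox + entry_axial
    # the duplex terminus (junction boundary) sits at the entry plane;
    # the first bp center lies one rise along the duplex axis inside it
    anchor = axis.origin + entry * d + offset * e1 + rise * target_dir

    R = _rotation_to(target_dir)
    placement = RigidTransform(R.rotation, anchor)  # bp 1 center -> anchor
    return duplex.transformed(placement)


@dataclass
class CompositeFixture:
    """A dismantled loader-clamp-DNA assembly with retained ground truth."""

    loader_dna_complex: Structure
    loader_clamp_complex: Structure
    true_dna_in_clamp_frame: DuplexModel
    true_tilt: float
    hidden_transforms: dict[str, RigidTransform] = field(default_factory=dict)
    anchor_chain: str = "V"


def make_composite_fixture(clamp_spec: SyntheticClampSpec | None = None,
                           dna_bp: int = 40,
                           tilt: float = 12.0,
                           loader_standoff: float = 12.0,
                           seed: int = 0,
                           identity_transforms: bool = False,
                           ) -> CompositeFixture:
    """Build a ground-truth loader+clamp+DNA assembly, then emit the two
    partial complexes in different frames related by hidden random rigid
    transforms (plus the ground truth for scoring).

    The pseudo-loader is five Calpha chains U-Y stacked against the
    clamp's proximal face; chain V plays the role of the anchor (B)
    subunit shared by the two complexes.  The DNA enters from the loader
    side (bp 1 inside the loader, ``loader_standoff`` Å below the
    proximal plane) and threads through the clamp at ``tilt`` degrees.
    """
    clamp_spec = clamp_spec or SyntheticClampSpec(seed=seed)
    rng = np.random.default_rng(seed)
    clamp = make_synthetic_clamp(clamp_spec)

    dna = make_tilted_duplex(clamp, tilt=tilt, offset=0.0, length=dna_bp,
                             seed=seed, entry_axial=-loader_standoff)

    # pseudo-loader: five Calpha blobs on an arc below the proximal face
    axis = ring_axis(clamp, n_fold=clamp_spec.n_fold)
    s_prox, _ = _face_planes(clamp, axis, 5.0, 95.0)
    loader_chains: dict[str, list[Residue]] = {}
    serial = 10_000
    for k, cid in enumerate("UVWXY"):
        ang = 2 * np.pi * k / 5
        center = (axis.origin
                  + (s_prox - 8.0 - 4.0 * k) * axis.direction
                  + 18.0 * np.array([np.cos(ang), np.sin(ang), 0.0]))
        residues = []
        for i in range(25):
            serial += 1
            xyz = center + rng.normal(0.0, 4.0, 3)
            residues.append(Residue(chain_id=cid, number=i + 1,
                                    name=PSEUDO_SEQUENCE[i % len(PSEUDO_SEQUENCE)],
                                    atoms=[Atom(serial=serial, name="CA",
                                                element="C", coord=xyz)]))
        loader_chains[cid] = residues

    def assemble(sid: str, parts: dict[str, list[Residue]]) -> Structure:
        s = Structure(id=sid)
        for cid, residues in parts.items():
            s.add_chain(cid, [r.copy() for r in residues])
        return s

    if identity_transforms:
        t1 = t2 = RigidTransform.identity()
    else:
        t1 = RigidTransform.random(rng)
        t2 = RigidTransform.random(rng)

    loader_dna = assemble("loader_dna", {
        **loader_chains,
        "1": dna.atoms.chains["1"],
        "2": dna.atoms.chains["2"],
    })
    loader_dna = loader_dna.with_coords(t1.apply(loader_dna.coords(primary_only=False)))

    loader_clamp = assemble("loader_clamp", {**loader_chains, **clamp.chains})
    loader_clamp = loader_clamp.with_coords(
        t2.apply(loader_clamp.coords(primary_only=False)))
    loader_clamp.metadata["n_fold"] = clamp_spec.n_fold
    loader_clamp.metadata["clamp_chains"] = [chr(ord("A") + k)
                                             for k in range(clamp_spec.n_fold)]

    return CompositeFixture(
        loader_dna_complex=loader_dna,
        loader_clamp_complex=loader_clamp,
        true_dna_in_clamp_frame=dna.transformed(t2),
        true_tilt=tilt,
        hidden_transforms={"loader_dna": t1, "loader_clamp": t2},
    )


# ---------------------------------------------------------------------------
# assay simulators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationSpec:
    """One-site anisotropy titration scenario: Y = Bmax X / (Kd + X) + noise."""

    kd: float = 100.0             # nM
    bmax: float = 0.12            # anisotropy units
    sigma: float = 0.006          # Gaussian noise SD (5% of Bmax)
    x: tuple = (25.0, 50.0, 100.0, 200.0, 400.0, 800.0)   # nM titrant
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class TimecourseSpec:
    """Linear NADH-depletion timecourse: A340 = a0 + slope * t + noise."""

    slope: float = -2e-4          # AU/s
    intercept: float = 1.0        # AU
    sigma: float = 1e-3           # AU
    t: tuple = tuple(float(v) for v in range(0, 601, 2))   # s
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def simulate_titration(spec: TitrationSpec) -> TitrationDataset:
    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.x, dtype=float)
    y = spec.bmax * x / (spec.kd + x)
    if spec.sigma > 0:
        y = y + rng.normal(0.0, spec.sigma, len(x))
    return TitrationDataset(x=x, y=y, label=spec.label,
                            metadata={"spec": spec, "seed": spec.seed})


def simulate_atpase_timecourse(spec: TimecourseSpec) -> Timecourse:
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.t, dtype=float)
    a = spec.intercept + spec.slope * t
    if spec.sigma > 0:
        a = a + rng.normal(0.0, spec.sigma, len(t))
    return Timecourse(t=t, a340=a, label=spec.label,
                      metadata={"spec": spec, "seed": spec.seed})
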