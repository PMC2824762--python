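"""Rigid-body superposition and clamp/DNA axis geometry.

The measurement core of the package: Kabsch least-squares superposition,
total-least-squares helical-axis fitting through base-pair centers,
ring-axis determination for pseudo-symmetric clamps, the tilt angle
between the two axes, and axial-span classification of how far a duplex
reaches through a clamp.

Conventions
-----------
* The ring axis is oriented proximal -> distal (the proximal face is the
  one binding the clamp loader), so axial coordinates increase as DNA
  threads through the ring away from the loader.
* Tilt angles are unsigned and folded to [0, 90] degrees.
* Clamp face planes are placed at configurable percentiles (default
  5th/95th) of the clamp Calpha axial coordinates, so surface loops do
  not inflate the apparent clamp thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import Structure

__all__ = [
    "RigidTransform",
    "RingAxis",
    "HelicalAxis",
    "SpanReport",
    "SpanSearch",
    "GeometryError",
    "InsufficientDataError",
    "FrameMismatchError",
    "kabsch_superpose",
    "apply_transform",
    "fit_helical_axis",
    "ring_axis",
    "tilt_angle",
    "axial_span",
    "min_bp_to_span",
]


class GeometryError(ValueError):
    """Degenerate geometry (collinear points, mismatched inputs, ...)."""


class InsufficientDataError(GeometryError):
    """Too few points for the requested fit."""


class FrameMismatchError(GeometryError):
    """Inputs do not appear to share a coordinate frame."""


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator,
               max_translation: float = 50.0) -> "RigidTransform":
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, 3)
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        """Composition: ``(A @ B).apply(x) == A.apply(B.apply(x))``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length direction vector")
    return v / n


@dataclass
class RingAxis:
    """Oriented symmetry axis of a ring-shaped clamp."""

    origin: np.ndarray
    direction: np.ndarray
    method: str
    n_fold: int
    quality: float           # per-subunit axis scatter, degrees
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = _unit(np.asarray(self.direction, dtype=float).reshape(3))
        if self.quality < 0:
            raise ValueError("quality must be >= 0")

    def axial_coordinates(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.direction


@dataclass
class HelicalAxis:
    """Best-fit straight axis through base-pair centers, oriented 5'->3'
    along strand 1."""

    point: np.ndarray
    direction: np.ndarray
    fit_rms: float           # perpendicular scatter, Å

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        self.direction = _unit(np.asarray(self.direction, dtype=float).reshape(3))
        if self.fit_rms < 0:
            raise ValueError("fit_rms must be >= 0")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     correspondence: list[tuple[int, int]] | None = None,
                     ) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper rigid superposition (Kabsch/SVD).

    Returns the transform mapping ``mobile`` onto ``target`` and the
    post-fit RMSD.  ``correspondence`` optionally pairs mobile/target
    indices; by default points correspond positionally.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if correspondence is not None:
        idx_m, idx_t = zip(*correspondence)
        mobile, target = mobile[list(idx_m)], target[list(idx_t)]
    if mobile.shape != target.shape:
        raise ValueError(f"point sets differ in shape: "
                         f"{mobile.shape} vs {target.shape}")
    n = len(mobile)
    if n < 3:
        raise InsufficientDataError("need >= 3 correspondences")

    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    m0, t0 = mobile - mc, target - tc
    if np.linalg.matrix_rank(t0, tol=1e-8) < 2 or \
       np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set")

    H = m0.T @ t0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tc - R @ mc
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mobile) - target) ** 2,
                                        axis=1))))
    return transform, rmsd


def apply_transform(t: RigidTransform, s: Structure) -> Structure:
    """Map every atom coordinate of ``s``; identifiers are untouched."""
    return s.with_coords(t.apply(s.coords(primary_only=False)))


# ---------------------------------------------------------------------------
# axes
# ---------------------------------------------------------------------------

def fit_helical_axis(centers: np.ndarray) -> HelicalAxis:
    """Total-least-squares line through ordered base-pair centers.

    The direction is the principal component of the centered point set,
    sign-oriented 5'->3' (from the first toward the last center);
    ``fit_rms`` is the RMS perpendicular scatter about the line.
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("centers must be an (n, 3) array")
    if len(pts) < 4:
        raise InsufficientDataError(
            f"need >= 4 base-pair centers, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    direction = Vt[0]
    if direction @ (pts[-1] - pts[0]) < 0:
        direction = -direction
    perp = centered - np.outer(centered @ direction, direction)
    fit_rms = float(np.sqrt(np.mean(np.sum(perp ** 2, axis=1))))
    return HelicalAxis(centroid, direction, fit_rms)


def _unit_calpha_sets(clamp: Structure, n_fold: int,
                      units: list[list[str]] | None) -> list[np.ndarray]:
    """Calpha coordinates per symmetry unit (chain-level by default)."""
    chain_ca = {cid: np.vstack([r.atom("CA").coord for r in residues
                                if r.has_atom("CA")])
                for cid, residues in clamp.chains.items()}
    if units is None:
        if len(chain_ca) != n_fold:
            raise ValueError(
                f"clamp has {len(chain_ca)} chains but n_fold={n_fold}; "
                f"supply an explicit unit (domain) map")
        units = [[cid] for cid in chain_ca]
    sets = [np.vstack([chain_ca[cid] for cid in unit]) for unit in units]
    counts = {len(s) for s in sets}
    if len(counts) != 1:
        raise ValueError(f"symmetry units have unequal Calpha counts {counts}; "
                         f"supply an alignment map")
    return sets


def ring_axis(clamp: Structure, n_fold: int, method: str = "symmetry",
              units: list[list[str]] | None = None,
              proximal_markers: np.ndarray | None = None) -> RingAxis:
    """Pseudo-symmetry (or plane-normal) axis of a ring-shaped clamp.

    ``symmetry``: superpose each unit onto the next (Calpha Kabsch),
    take each rotation's axis, and average; ``quality`` is the maximum
    pairwise angular scatter between the per-step axes, in degrees.  A
    rotation angle deviating more than 15 degrees from 360/n is recorded
    as a warning.  ``plane``: unit normal of the total-least-squares
    plane through all Calpha.  The direction is oriented proximal ->
    distal: when ``proximal_markers`` (coordinates on the loader-binding
    face) are given, they end up at negative axial coordinates.
    """
    if method not in ("symmetry", "plane"):
        raise ValueError(f"unknown ring-axis method {method!r}")
    sets = _unit_calpha_sets(clamp, n_fold, units)
    all_ca = np.vstack(sets)
    origin = all_ca.mean(axis=0)
    warnings: list[str] = []

    if method == "plane":
        centered = all_ca - origin
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        direction = Vt[-1]
        quality = 0.0
    else:
        expected = 360.0 / n_fold
        axes = []
        for i in range(n_fold):
            transform, _ = kabsch_superpose(sets[i], sets[(i + 1) % n_fold])
            rotvec = Rotation.from_matrix(transform.rotation).as_rotvec()
            angle = np.degrees(np.linalg.norm(rotvec))
            if angle < 1e-9:
                raise GeometryError(
                    f"unit {i}->{i + 1} superposition has no rotation; "
                    f"not a ring?")
            axis = rotvec / np.linalg.norm(rotvec)
            if abs(angle - expected) > 15.0:
                warnings.append(
                    f"unit {i}->{i + 1} rotation angle {angle:.1f} deg deviates "
                    f"from 360/{n_fold} = {expected:.1f} deg")
            axes.append(axis)
        axes = np.array(axes)
        # align signs to the first axis before averaging
        for k in range(1, len(axes)):
            if axes[k] @ axes[0] < 0:
                axes[k] = -axes[k]
        direction = _unit(axes.mean(axis=0))
        quality = 0.0
        for a in range(len(axes)):
            for b in range(a + 1, len(axes)):
                dot = np.clip(abs(axes[a] @ axes[b]), -1.0, 1.0)
                quality = max(quality, float(np.degrees(np.arccos(dot))))

    if proximal_markers is not None:
        markers = np.asarray(proximal_markers, dtype=float).reshape(-1, 3)
        if (markers.mean(axis=0) - origin) @ direction > 0:
            direction = -direction
    else:
        # deterministic sign: largest-magnitude component positive
        k = int(np.argmax(np.abs(direction)))
        if direction[k] < 0:
            direction = -direction
    return RingAxis(origin, direction, method, n_fold, quality, warnings)


def tilt_angle(h: HelicalAxis | np.ndarray, r: RingAxis | np.ndarray) -> float:
    """Unsigned angle between helical and ring axes, degrees in [0, 90]."""
    hv = h.direction if isinstance(h, HelicalAxis) else _unit(np.asarray(h, float))
    rv = r.direction if isinstance(r, RingAxis) else _unit(np.asarray(r, float))
    return float(np.degrees(np.arccos(np.clip(abs(hv @ rv), 0.0, 1.0))))


# ---------------------------------------------------------------------------
# axial span
# ---------------------------------------------------------------------------

@dataclass
class SpanReport:
    """How far a duplex reaches through a clamp along its ring axis.

    ``axial`` is the per-bp projection onto the ring axis in Å, zero at
    the proximal face plane and increasing toward the distal face.
    """

    axial: np.ndarray
    clamp_thickness: float
    classification: str
    proximal_plane: float     # absolute axial coordinate of the proximal plane
    distal_plane: float
    opening_margin: float
    monotone: bool


def _face_planes(clamp: Structure, ring: RingAxis,
                 proximal_percentile: float,
                 distal_percentile: float) -> tuple[float, float]:
    ca = clamp.coords(atom_name="CA")
    if len(ca) == 0:
        raise ValueError("clamp has no Calpha atoms")
    s = ring.axial_coordinates(ca)
    return (float(np.percentile(s, proximal_percentile)),
            float(np.percentile(s, distal_percentile)))


def _classify(u_term: float, thickness: float, margin: float) -> str:
    if u_term > thickness:
        return "through"
    if abs(u_term) <= margin:
        return "opening"
    if u_term > margin:
        return "partial"
    return "outside"


def axial_span(d, r: RingAxis, clamp: Structure,
               proximal_percentile: float = 5.0,
               distal_percentile: float = 95.0,
               opening_margin: float = 4.0) -> SpanReport:
    """Project a duplex's bp centers onto the ring axis and classify the
    terminal base pair: ``through`` (beyond the distal face plane),
    ``partial`` (between the planes), ``opening`` (within the margin of
    the proximal plane; default 4 Å ~ one bp rise) or ``outside``.

    ``d`` may be a DuplexModel or a raw (n, 3) array of bp centers with
    index 0 at the loader-proximal terminus.
    """
    centers = np.asarray(getattr(d, "bp_centers", d), dtype=float)
    if np.min(np.linalg.norm(centers - r.origin, axis=1)) > 50.0:
        raise FrameMismatchError(
            "duplex is entirely > 50 Å from the ring centroid; inputs "
            "probably do not share a frame (untransformed component?)")
    s_prox, s_dist = _face_planes(clamp, r, proximal_percentile,
                                  distal_percentile)
    thickness = s_dist - s_prox
    axial = r.axial_coordinates(centers) - s_prox
    diffs = np.diff(axial)
    monotone = bool(np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9))
    classification = _classify(float(axial[-1]), thickness, opening_margin)
    return SpanReport(axial, thickness, classification,
                      s_prox, s_dist, opening_margin, monotone)


@dataclass
class SpanSearch:
    """Result of scanning duplex truncation lengths against a clamp."""

    min_bp: int | None
    bounded: bool
    max_examined: int
    classifications: list[str]


def min_bp_to_span(d, r: RingAxis, clamp: Structure,
                   **span_kwargs) -> SpanSearch:
    """Smallest duplex length (bp 1 = loader-proximal terminus fixed)
    whose terminal base pair classifies as ``through``.

    Truncations keep bp 1 fixed and shorten from the far (blunt) end,
    mirroring how primer-template constructs of decreasing duplex length
    share the junction end.  If even the full duplex never reaches the
    distal plane the search is reported as unbounded.
    """
    centers = np.asarray(getattr(d, "bp_centers", d), dtype=float)
    n = len(centers)
    report = axial_span(centers, r, clamp, **span_kwargs)
    classifications = [
        _classify(float(report.axial[length - 1]), report.clamp_thickness,
                  report.opening_margin)
        for length in range(1, n + 1)
    ]
    for length, cls in enumerate(classifications, start=1):
        if cls == "through":
            return SpanSearch(length, True, n, classifications)
    return SpanSearch(None, False, n, classifications)
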