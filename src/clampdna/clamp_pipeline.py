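"""Composite clamp-loader / clamp / DNA model construction and contact
analysis.

The composite build follows the anchored-superposition recipe used to
visualize DNA passing through a loaded clamp: two crystal structures —
a loader bound to primer-template DNA and a loader bound to a closed
clamp — share an equivalent anchor subunit (the B subunit of the
pentamer).  Superposing the clamp complex's anchor chain onto the DNA
complex's anchor chain (Calpha Kabsch) gives a transform whose inverse
transfers the DNA into the clamp complex's frame; an ideal B-form
duplex is then aligned onto the end of the transferred DNA to extend it
through the ring.  Every stage is logged with its parameters and
transform so a build can be replayed bit-identically.

Contact analysis is purely geometric: closed-interval distance cutoffs
between atom sets (default 4.0 Å, a typical salt-bridge/H-bond
heavy-atom distance), a formal inventory of Lys/Arg on the helices
lining the clamp's central hole, and a per-mutant-set report of which
mutated residues actually touch or approach the modeled DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import dna_builder
from .dna_builder import DuplexModel, build_bform_duplex, reverse_complement
from .geometry import RigidTransform, kabsch_superpose
from .structio import Residue, Structure, select

__all__ = [
    "CompositeModel",
    "AnchorError",
    "build_composite_model",
    "replay_composite",
    "duplex_from_structure",
    "find_contacts",
    "basic_residue_inventory",
    "mutation_set_report",
    "PHOSPHATE_ATOMS",
    "PCNA_HELIX_RANGES",
    "MUTANT_SETS",
]

#: Backbone phosphate-group atoms used by the ``phosphate`` contact filter.
PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "O5'", "O3'"}

#: Default author-numbering ranges for the alpha-helices lining the
#: central hole of the eukaryotic clamp (two helix pairs per domain of
#: the trimer-of-dimers architecture).  Derived from inspection of the
#: deposited clamp's secondary structure; override per structure.
PCNA_HELIX_RANGES = [(8, 24), (70, 82), (139, 152), (204, 216)]

#: The combination mutants assayed against clamp-loader ATPase activity.
MUTANT_SETS = {
    "domain1_triple": ["K20A", "K77A", "R80A"],
    "domain2_triple": ["K146A", "R149A", "K210A"],
    "loading_quadruple": ["K20A", "K77A", "R80A", "R149A"],
    "xray_contact_quadruple": ["K13A", "R14A", "K146A", "R149A"],
    "his190_loop": ["H190A", "T193A"],
    "asn84_loop": ["N83A", "N84A", "T85A"],
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}


class AnchorError(ValueError):
    """Anchor-chain superposition failed or looks wrong."""


@dataclass
class CompositeModel:
    """An assembled loader-clamp-DNA coordinate set with full provenance.

    ``components`` maps role -> (structure, placing transform, source id);
    ``duplex`` is the transferred-and-extended DNA in the clamp-complex
    frame; ``log`` records every stage with its parameters, so replaying
    the log on the same inputs reproduces the coordinates bit-for-bit.
    """

    components: dict[str, tuple[Structure, RigidTransform, str]]
    duplex: DuplexModel
    chain_map: tuple[str, str]
    anchor_rmsd: float
    log: list[dict] = field(default_factory=list)
    clash_warnings: list[dict] = field(default_factory=list)

    def structure(self) -> Structure:
        """Merged coordinates: the clamp complex plus the placed DNA."""
        base = self.components["loader_clamp"][0].copy()
        dna = self.duplex.atoms
        for cid, residues in dna.chains.items():
            out_cid = cid
            while out_cid in base.chains:
                out_cid = out_cid + "'"
            base.add_chain(out_cid, [r.copy() for r in residues])
        base.id = "composite"
        return base


def _calpha_coords(chain: list[Residue]) -> np.ndarray:
    return np.vstack([r.atom("CA").coord for r in chain if r.has_atom("CA")])


def _chain_sequence(chain: list[Residue]) -> str:
    return "".join(_THREE_TO_ONE.get(r.name, "X")
                   for r in chain if r.has_atom("CA"))


def _aligned_calpha_pairs(chain_a: list[Residue], chain_b: list[Residue]
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Sequence-equivalent Calpha coordinate pairs for two chains.

    Equal-length chains correspond positionally; otherwise a global
    alignment of the two sequences supplies the equivalences.
    """
    ca_a = [r for r in chain_a if r.has_atom("CA")]
    ca_b = [r for r in chain_b if r.has_atom("CA")]
    if len(ca_a) == len(ca_b):
        return (np.vstack([r.atom("CA").coord for r in ca_a]),
                np.vstack([r.atom("CA").coord for r in ca_b]))
    from Bio import Align
    aligner = Align.PairwiseAligner(mode="global",
                                    open_gap_score=-10, extend_gap_score=-0.5,
                                    match_score=2, mismatch_score=-1)
    alignment = aligner.align(_chain_sequence(ca_a), _chain_sequence(ca_b))[0]
    idx_a, idx_b = [], []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        idx_a.extend(range(a0, a1))
        idx_b.extend(range(b0, b1))
    if len(idx_a) < 3:
        raise AnchorError("anchor chains share fewer than 3 alignable residues")
    return (np.vstack([ca_a[i].atom("CA").coord for i in idx_a]),
            np.vstack([ca_b[i].atom("CA").coord for i in idx_b]))


def _dna_substructure(s: Structure, dna_chains: list[str] | None) -> Structure:
    if dna_chains:
        out = Structure(id=s.id + "_dna")
        for cid in dna_chains:
            out.add_chain(cid, [r.copy() for r in s.chains[cid]])
        return out
    return select(s, "kind dna")


def duplex_from_structure(s: Structure,
                          chain_pair: tuple[str, str] | None = None) -> DuplexModel:
    """Reconstruct a :class:`DuplexModel` from a two-chain DNA structure.

    Residue k of the first chain is paired with residue n-1-k of the
    second (antiparallel register, verified Watson-Crick); bp centers
    are C1' midpoints.  Deposited strand labels are honored: the first
    chain in iteration order is strand 1.
    """
    dna = select(s, "kind dna")
    cids = list(dna.chains)
    if chain_pair is not None:
        cids = list(chain_pair)
    if len(cids) != 2:
        raise ValueError(f"expected exactly 2 DNA chains, found {cids}")
    chain1, chain2 = dna.chains[cids[0]], dna.chains[cids[1]]
    if len(chain1) != len(chain2):
        raise ValueError("DNA strands differ in modeled length; cannot pair")
    n = len(chain1)
    name_to_base = {"DA": "A", "DC": "C", "DG": "G", "DT": "T",
                    "A": "A", "C": "C", "G": "G", "T": "T"}
    seq1 = "".join(name_to_base[r.name] for r in chain1)
    seq2 = "".join(name_to_base[r.name] for r in chain2)
    if reverse_complement(seq1) != seq2:
        raise ValueError("chains are not exact antiparallel complements")

    atoms = Structure(id=s.id + "_duplex")
    atoms.add_chain("1", [r.copy() for r in chain1])
    atoms.add_chain("2", [r.copy() for r in chain2])
    # renumber to 1..n / 1..n so pairing indices are positional
    for k, r in enumerate(atoms.chains["1"]):
        r.number = k + 1
    for k, r in enumerate(atoms.chains["2"]):
        r.number = k + 1
    pairing = [(k, n - 1 - k) for k in range(n)]
    centers = np.vstack([
        0.5 * (atoms.chains["1"][k].atom("C1'").coord
               + atoms.chains["2"][n - 1 - k].atom("C1'").coord)
        for k in range(n)])
    spacing = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    rise = float(np.median(spacing)) if len(spacing) else dna_builder.B_FORM_RISE
    return DuplexModel(seq1, seq2, pairing, atoms, centers, rise=rise)


def _extend_duplex(duplex: DuplexModel, extension_length: int,
                   rise: float, twist: float,
                   extension_seq: str | None,
                   anchor_bp: int = 4) -> tuple[DuplexModel, dict]:
    """Append ideal B-form base pairs past the duplex's strand-1 3' end.

    An ideal duplex is built for the last ``anchor_bp`` transferred base
    pairs plus the extension, superposed onto the transferred anchor
    C1' atoms, and its extra base pairs appended.
    """
    n = duplex.n_bp
    if anchor_bp > n:
        raise ValueError(f"extension anchor needs {anchor_bp} bp, duplex has {n}")
    ext_seq = (extension_seq or "A" * extension_length).upper()
    if len(ext_seq) != extension_length:
        raise ValueError("extension sequence length mismatch")

    anchor_seq = duplex.duplex_seq1[-anchor_bp:]
    ideal = build_bform_duplex(anchor_seq + ext_seq, rise=rise, twist=twist,
                               phosphate5_strand1=True, phosphate5_strand2=True)

    def c1_pairs(d: DuplexModel, ks: list[int]) -> np.ndarray:
        res1 = {r.number: r for r in d.atoms.chains["1"]}
        res2 = {r.number: r for r in d.atoms.chains["2"]}
        pts = []
        for k in ks:
            i, j = d.pairing[k]
            pts.append(res1[i + 1].atom("C1'").coord)
            pts.append(res2[j + 1].atom("C1'").coord)
        return np.vstack(pts)

    target = c1_pairs(duplex, list(range(n - anchor_bp, n)))
    mobile = c1_pairs(ideal, list(range(anchor_bp)))
    transform, rmsd = kabsch_superpose(mobile, target)

    placed = ideal.transformed(transform)
    res1 = {r.number: r for r in placed.atoms.chains["1"]}
    res2 = {r.number: r for r in placed.atoms.chains["2"]}

    new_seq1 = duplex.duplex_seq1 + ext_seq
    new_seq2 = reverse_complement(new_seq1)
    total = n + extension_length
    atoms = Structure(id=duplex.atoms.id + "_extended")
    chain1 = [r.copy() for r in duplex.atoms.chains["1"]]
    # renumber residues to match the extended strand indices: the
    # extension sits at strand 2's 5' end, shifting old strand-2 indices
    # up by extension_length
    for k, r in enumerate(chain1):
        r.number = k + 1
    old_chain2 = [r.copy() for r in duplex.atoms.chains["2"]]
    for k, r in enumerate(old_chain2):
        r.number = extension_length + k + 1
    ext_chain2 = []
    for e in range(extension_length):
        k = anchor_bp + e            # bp index within the ideal duplex
        i, j = placed.pairing[k]
        r1 = res1[i + 1].copy()
        r1.number = n + e + 1
        chain1.append(r1)
        r2 = res2[j + 1].copy()
        r2.number = extension_length - e   # strand-2 index (total-1-k) + 1
        ext_chain2.append(r2)
    ext_chain2.reverse()             # 5'->3' = ascending residue numbers
    atoms.add_chain("1", chain1)
    atoms.add_chain("2", ext_chain2 + old_chain2)
    pairing = [(k, total - 1 - k) for k in range(total)]
    centers = np.vstack([duplex.bp_centers, placed.bp_centers[anchor_bp:]])
    extended = DuplexModel(new_seq1, new_seq2, pairing, atoms,
                           centers, rise=rise, twist=twist)
    info = {"anchor_bp": anchor_bp, "anchor_rmsd": rmsd,
            "transform": transform.to_dict(), "extension_seq": ext_seq}
    return extended, info


def build_composite_model(loader_dna_complex: Structure,
                          loader_clamp_complex: Structure,
                          anchor_chain_pair: tuple[str, str],
                          extension_length: int = 0,
                          dna_params: dict | None = None,
                          dna_chains: tuple[str, str] | None = None,
                          clash_cutoff: float = 1.5,
                          max_anchor_rmsd: float = 5.0) -> CompositeModel:
    """Assemble the clamp-loader / clamp / DNA composite model.

    Stage 1: Kabsch-superpose the clamp complex's anchor chain onto the
    DNA complex's anchor chain (Calpha, sequence-equivalent positions).
    Stage 2: transfer the DNA into the clamp complex's frame via the
    inverse transform.  Stage 3 (optional): extend the transferred
    duplex by ``extension_length`` ideal B-form base pairs aligned on
    its last 4 bp.  Extended-DNA atoms closer than ``clash_cutoff`` to
    any clamp-complex atom are recorded as warnings, not errors.
    """
    params = {"rise": dna_builder.B_FORM_RISE,
              "twist": dna_builder.B_FORM_TWIST,
              "extension_seq": None,
              "anchor_bp": 4}
    params.update(dna_params or {})
    cid_dna, cid_clamp = anchor_chain_pair
    for cid, s, name in ((cid_dna, loader_dna_complex, "DNA complex"),
                         (cid_clamp, loader_clamp_complex, "clamp complex")):
        if cid not in s.chains:
            raise AnchorError(f"anchor chain {cid!r} absent from the {name}")

    target, mobile = _aligned_calpha_pairs(loader_dna_complex.chains[cid_dna],
                                           loader_clamp_complex.chains[cid_clamp])
    transform, rmsd = kabsch_superpose(mobile, target)
    if rmsd > max_anchor_rmsd:
        raise AnchorError(
            f"anchor superposition rmsd {rmsd:.2f} Å exceeds "
            f"{max_anchor_rmsd} Å; wrong chains?")

    log = [{"stage": "anchor_superposition",
            "anchor_chain_pair": list(anchor_chain_pair),
            "rmsd": rmsd, "transform": transform.to_dict()}]

    inverse = transform.inverse()
    dna_structure = _dna_substructure(loader_dna_complex, list(dna_chains)
                                      if dna_chains else None)
    if not dna_structure.chains:
        raise ValueError("no DNA chains found in the DNA complex")
    dna_in_clamp = dna_structure.with_coords(
        inverse.apply(dna_structure.coords(primary_only=False)))
    duplex = duplex_from_structure(dna_in_clamp)
    log.append({"stage": "dna_transfer", "transform": inverse.to_dict(),
                "dna_chains": list(dna_structure.chains)})

    if extension_length > 0:
        duplex, ext_info = _extend_duplex(
            duplex, extension_length, params["rise"], params["twist"],
            params["extension_seq"], params["anchor_bp"])
        log.append({"stage": "extension",
                    "extension_length": extension_length, **ext_info})

    clash_warnings: list[dict] = []
    if extension_length > 0:
        clamp_coords = loader_clamp_complex.coords(primary_only=False)
        tree = cKDTree(clamp_coords)
        n_old = duplex.n_bp - extension_length
        for cid, residues in duplex.atoms.chains.items():
            for r in residues:
                # extension residues: strand 1 numbers > n_old; strand 2
                # numbers <= extension_length (its 5' end)
                is_ext = (r.number > n_old if cid == "1"
                          else r.number <= extension_length)
                if not is_ext:
                    continue
                for a in r.atoms:
                    hits = tree.query_ball_point(a.coord, clash_cutoff)
                    if hits:
                        clash_warnings.append(
                            {"strand": cid, "residue": r.number,
                             "atom": a.name, "n_clamp_atoms": len(hits)})

    components = {
        "loader_dna": (loader_dna_complex, RigidTransform.identity(),
                       loader_dna_complex.id),
        "loader_clamp": (loader_clamp_complex, RigidTransform.identity(),
                         loader_clamp_complex.id),
        "dna": (dna_in_clamp, inverse, loader_dna_complex.id),
    }
    log.append({"stage": "done",
                "params": {"extension_length": extension_length,
                           "rise": params["rise"], "twist": params["twist"],
                           "anchor_bp": params["anchor_bp"]}})
    return CompositeModel(components, duplex, anchor_chain_pair, rmsd, log,
                          clash_warnings)


def replay_composite(log: list[dict], loader_dna_complex: Structure,
                     loader_clamp_complex: Structure) -> CompositeModel:
    """Re-run a composite build from its provenance log.

    The build is a pure function of its inputs and logged parameters, so
    the replay reproduces coordinates bit-identically.
    """
    anchor = tuple(log[0]["anchor_chain_pair"])
    done = next(e for e in log if e["stage"] == "done")
    p = done["params"]
    ext_entries = [e for e in log if e["stage"] == "extension"]
    dna_params = {"rise": p["rise"], "twist": p["twist"],
                  "anchor_bp": p["anchor_bp"],
                  "extension_seq": ext_entries[0]["extension_seq"]
                  if ext_entries else None}
    return build_composite_model(loader_dna_complex, loader_clamp_complex,
                                 anchor, p["extension_length"], dna_params)


# ---------------------------------------------------------------------------
# contacts and inventories
# ---------------------------------------------------------------------------

_BACKBONE_PROTEIN = {"N", "CA", "C", "O", "OXT", "CB"}


def _atom_rows(s: Structure, role: str, atom_filter: str) -> list[tuple]:
    rows = []
    for r, a in s.atoms():
        if not a.primary or a.is_hydrogen or r.is_solvent:
            continue
        if role == "dna" and atom_filter == "phosphate" \
                and a.name not in PHOSPHATE_ATOMS:
            continue
        if role == "protein" and atom_filter == "sidechain_polar":
            if a.element.upper() not in ("N", "O") or a.name in _BACKBONE_PROTEIN:
                continue
        rows.append((r.chain_id, r.number, r.name, a.name, a.coord))
    return rows


def find_contacts(protein: Structure, dna: Structure, cutoff: float = 4.0,
                  dna_atom_filter: str = "all",
                  protein_atom_filter: str = "all") -> pd.DataFrame:
    """All protein/DNA atom pairs within a closed-interval cutoff.

    ``dna_atom_filter='phosphate'`` restricts DNA atoms to the backbone
    phosphate group (P, OP1, OP2, O5', O3'); ``protein_atom_filter=
    'sidechain_polar'`` keeps only side-chain N/O atoms beyond Cbeta.
    Empty selections yield an empty table.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if dna_atom_filter not in ("phosphate", "all"):
        raise ValueError(f"unknown dna_atom_filter {dna_atom_filter!r}")
    if protein_atom_filter not in ("sidechain_polar", "all"):
        raise ValueError(f"unknown protein_atom_filter {protein_atom_filter!r}")

    prot = _atom_rows(protein, "protein", protein_atom_filter)
    nuc = _atom_rows(dna, "dna", dna_atom_filter)
    columns = ["protein_chain", "residue_number", "residue_name",
               "protein_atom", "dna_strand", "base_index", "dna_atom",
               "distance"]
    if not prot or not nuc:
        return pd.DataFrame(columns=columns)

    ptree = cKDTree(np.vstack([p[4] for p in prot]))
    ntree = cKDTree(np.vstack([q[4] for q in nuc]))
    pairs = ptree.query_ball_tree(ntree, r=cutoff)
    rows = []
    for ip, hits in enumerate(pairs):
        for iq in hits:
            d = float(np.linalg.norm(prot[ip][4] - nuc[iq][4]))
            if d > cutoff:       # guard: closed interval exactly at cutoff
                continue
            rows.append((prot[ip][0], prot[ip][1], prot[ip][2], prot[ip][3],
                         nuc[iq][0], nuc[iq][1], nuc[iq][3], round(d, 4)))
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values(columns[:7], ignore_index=True) if len(df) else df


def basic_residue_inventory(clamp: Structure,
                            helix_residue_ranges: list[tuple[int, int]]
                            = tuple(PCNA_HELIX_RANGES)) -> pd.DataFrame:
    """Lys/Arg residues on the helices lining the clamp's central hole.

    ``helix_residue_ranges`` uses author numbering.  Returns one row per
    (chain, residue); per-subunit counts other than the canonical nine
    are surfaced in the caller's hands, not silently adjusted.
    """
    numbers = set()
    max_resnum = max((r.number for r in clamp.residues()), default=0)
    for lo, hi in helix_residue_ranges:
        if lo > max_resnum:
            raise ValueError(f"range {lo}-{hi} lies outside the structure "
                             f"(last residue {max_resnum})")
        numbers.update(range(lo, hi + 1))
    rows = [{"chain": r.chain_id, "residue_number": r.number,
             "residue_name": r.name}
            for r in clamp.residues()
            if r.name in ("LYS", "ARG") and r.number in numbers]
    return pd.DataFrame(rows, columns=["chain", "residue_number",
                                       "residue_name"])


def _parse_mutation(code: str) -> tuple[str, int]:
    """'K20A' -> ('LYS', 20); the target residue type is checked, the
    substituted type (trailing letter) is informational."""
    code = code.strip().upper()
    if len(code) < 3 or not code[0].isalpha() or not code[-1].isalpha():
        raise ValueError(f"malformed mutation code {code!r}")
    wt, num = code[0], code[1:-1]
    if wt not in _ONE_TO_THREE or not num.isdigit():
        raise ValueError(f"malformed mutation code {code!r}")
    return _ONE_TO_THREE[wt], int(num)


def mutation_set_report(clamp: Structure,
                        mutant_sets: dict[str, list[str]] | None = None,
                        contact_table: pd.DataFrame | None = None,
                        dna: Structure | None = None,
                        proximity_cutoff: float = 6.0) -> pd.DataFrame:
    """For each mutant set, which members contact DNA and how close they
    come to the modeled duplex.

    A member is ``in_contact`` if any contact-table row carries its
    residue number (any subunit); ``min_distance`` is the closest
    heavy-atom approach of that residue (over all subunits) to ``dna``.
    Unknown residues raise a validation error.
    """
    mutant_sets = mutant_sets if mutant_sets is not None else MUTANT_SETS
    by_number: dict[int, list[Residue]] = {}
    for r in clamp.residues():
        by_number.setdefault(r.number, []).append(r)

    dna_tree = None
    if dna is not None:
        dna_coords = np.vstack([a.coord for _, a in dna.atoms()
                                if a.primary and not a.is_hydrogen])
        dna_tree = cKDTree(dna_coords)

    contact_numbers: set[int] = set()
    if contact_table is not None and len(contact_table):
        contact_numbers = set(contact_table["residue_number"].tolist())

    rows = []
    for set_name, members in mutant_sets.items():
        for code in members:
            resname, resnum = _parse_mutation(code)
            candidates = [r for r in by_number.get(resnum, [])
                          if r.name == resname]
            if not candidates:
                raise ValueError(
                    f"mutant set {set_name!r}: residue {code} "
                    f"({resname} {resnum}) not found in the clamp")
            row = {"mutant_set": set_name, "mutation": code,
                   "residue_name": resname, "residue_number": resnum,
                   "n_subunits": len(candidates),
                   "in_contact": resnum in contact_numbers
                   if contact_table is not None else None,
                   "min_distance": None, "within_cutoff": None}
            if dna_tree is not None:
                coords = np.vstack([a.coord for r in candidates
                                    for a in r.atoms
                                    if a.primary and not a.is_hydrogen])
                d, _ = dna_tree.query(coords)
                row["min_distance"] = round(float(np.min(d)), 3)
                row["within_cutoff"] = bool(np.min(d) <= proximity_cutoff)
            rows.append(row)
    return pd.DataFrame(rows)
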