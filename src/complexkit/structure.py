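"""Structural mutual-exclusivity calling from pairwise dimer models.

Two predicted dimer models that share a common subunit (A–C and B–C) are
superposed on the shared chain C; if the unique subunits A and B then
occupy overlapping interfaces on C, they cannot bind C simultaneously and
the pair is called mutually exclusive. Models are first quality-filtered
on pDockQ, interface pLDDT and inter-chain clashes. The superposition is
a sequence-matched Cα Kabsch fit; interfaces are defined by heavy-atom
distance to the common chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .pairs import canonical_pair

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # Å

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    seqid: int
    name: str
    atoms: List[Atom]
    plddt: float = 0.0

    def heavy_coords(self) -> np.ndarray:
        coords = [a.xyz for a in self.atoms if not a.is_hydrogen]
        return np.asarray(coords, dtype=float).reshape(-1, 3)

    def ca(self) -> Optional[np.ndarray]:
        for a in self.atoms:
            if a.name == "CA":
                return a.xyz
        return None


@dataclass
class Chain:
    accession: str
    chain_id: str
    residues: List[Residue]

    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def heavy_coords(self) -> Tuple[np.ndarray, np.ndarray]:
        """(coords, residue index per atom) over heavy atoms."""
        coords, idx = [], []
        for i, r in enumerate(self.residues):
            for a in r.atoms:
                if not a.is_hydrogen:
                    coords.append(a.xyz)
                    idx.append(i)
        return np.asarray(coords, dtype=float).reshape(-1, 3), np.asarray(idx, dtype=int)


@dataclass
class StructuralModel:
    model_id: str
    chains: List[Chain]
    pdockq: Optional[float] = None
    if_plddt: Optional[float] = None
    source: str = ""

    def __post_init__(self):
        if len(self.chains) != 2:
            raise ValueError(f"model {self.model_id!r} must have exactly 2 chains")
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    if not np.all(np.isfinite(a.xyz)):
                        raise ValueError("non-finite coordinates")
                if not 0 <= r.plddt <= 100:
                    raise ValueError("pLDDT outside [0, 100]")

    def chain_for(self, accession: str) -> Chain:
        for c in self.chains:
            if c.accession == accession:
                return c
        raise KeyError(f"model {self.model_id!r} has no chain for {accession!r}")

    def other_chain(self, accession: str) -> Chain:
        others = [c for c in self.chains if c.accession != accession]
        if len(others) != 1:
            raise KeyError(f"model {self.model_id!r}: cannot resolve unique chain")
        return others[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructuralModel":
        chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [
                    Atom(a.name, a.element, rotation @ a.xyz + translation)
                    for a in r.atoms
                ]
                residues.append(Residue(r.seqid, r.name, atoms, r.plddt))
            chains.append(Chain(c.accession, c.chain_id, residues))
        return StructuralModel(self.model_id, chains, self.pdockq, self.if_plddt, self.source)


# ---------------------------------------------------------------------------
# I/O (PDB / mmCIF via gemmi)


def read_model(path, accession_map: Optional[Mapping[str, str]] = None) -> StructuralModel:
    """Read a two-chain model from PDB or mmCIF.

    Chain-to-accession mapping comes from ``accession_map`` (chain id ->
    accession) or from the ``ACC1__ACC2`` file-naming convention, assigning
    accessions to chains in order. Per-residue pLDDT is taken from the
    B-factor column.
    """
    import gemmi

    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = []
    name_accs = path.stem.split("__") if "__" in path.stem else None
    for i, ch in enumerate(model):
        residues = []
        for res in ch:
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in res
            ]
            plddt = float(np.mean([a.b_iso for a in res])) if len(res) else 0.0
            residues.append(Residue(res.seqid.num, res.name, atoms, plddt))
        if accession_map and ch.name in accession_map:
            acc = accession_map[ch.name]
        elif name_accs and i < len(name_accs):
            acc = name_accs[i]
        else:
            acc = ch.name
        chains.append(Chain(acc, ch.name, residues))
    if len(chains) != 2:
        raise ValueError(f"{path}: expected 2 chains, found {len(chains)}")
    return StructuralModel(path.stem, chains)


def write_model(model: StructuralModel, path) -> None:
    """Write a model to PDB with pLDDT in the B-factor column."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain, cid in zip(model.chains, ("A", "B")):
        gc = gemmi.Chain(chain.chain_id or cid)
        for r in chain.residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.seqid, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*map(float, a.xyz))
                ga.b_iso = float(r.plddt)
                ga.occ = 1.0
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Quality filtering


def count_clashing_residues(model: StructuralModel, clash_distance: float = 2.0) -> int:
    """Distinct residues (both chains) with a heavy atom within ``clash_distance``
    of the other chain."""
    (xa, ia), (xb, ib) = model.chains[0].heavy_coords(), model.chains[1].heavy_coords()
    if len(xa) == 0 or len(xb) == 0:
        return 0
    tree = cKDTree(xb)
    close_a = tree.query_ball_point(xa, clash_distance)
    res_a = {ia[i] for i, hits in enumerate(close_a) if hits}
    res_b = {ib[j] for hits in close_a for j in hits}
    return len(res_a) + len(res_b)


def interface_residues(chain: Chain, other: Chain, cutoff: float = 4.0) -> Set[int]:
    """Indices of ``chain`` residues with any heavy atom <= cutoff from ``other``."""
    xc, ic = chain.heavy_coords()
    xo, _ = other.heavy_coords()
    if len(xc) == 0 or len(xo) == 0:
        return set()
    tree = cKDTree(xo)
    close = tree.query_ball_point(xc, cutoff)
    return {int(ic[i]) for i, hits in enumerate(close) if hits}


def pdockq_from_model(model: StructuralModel, cutoff: float = 4.0) -> Tuple[float, float]:
    """(pDockQ, interface pLDDT) from coordinates via the published logistic.

    pDockQ = 0.724 / (1 + exp(-0.052 (x - 152.611))) + 0.018 with
    x = mean interface pLDDT * log10(number of interface residues), and the
    interface defined at ``cutoff`` Å between heavy atoms.
    """
    a, b = model.chains
    ifa = interface_residues(a, b, cutoff)
    ifb = interface_residues(b, a, cutoff)
    n_if = len(ifa) + len(ifb)
    if n_if == 0:
        return 0.018, 0.0
    plddts = [a.residues[i].plddt for i in ifa] + [b.residues[i].plddt for i in ifb]
    if_plddt = float(np.mean(plddts))
    x = if_plddt * math.log10(n_if)
    pdockq = 0.724 / (1 + math.exp(-0.052 * (x - 152.611))) + 0.018
    return pdockq, if_plddt


def filter_models(
    models: Iterable[StructuralModel],
    pdockq_min: float = 0.23,
    if_plddt_min: float = 70.0,
    clash_max: int = 5,
    clash_distance: float = 2.0,
) -> List[StructuralModel]:
    """Retain models with pDockQ > pdockq_min, interface pLDDT > if_plddt_min
    (both strict) and fewer than ``clash_max`` clashing residues (strict <).

    Metadata, when present on the model, wins; otherwise pDockQ and the
    interface pLDDT are computed from coordinates.
    """
    kept = []
    for m in models:
        pdockq, if_plddt = m.pdockq, m.if_plddt
        if pdockq is None or if_plddt is None:
            computed = pdockq_from_model(m)
            pdockq = pdockq if pdockq is not None else computed[0]
            if_plddt = if_plddt if if_plddt is not None else computed[1]
        if pdockq <= pdockq_min or if_plddt <= if_plddt_min:
            continue
        if count_clashing_residues(m, clash_distance) >= clash_max:
            continue
        kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# Superposition


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int


def _kabsch(P: np.ndarray, Q: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping P onto Q (proper rotation)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return R, t, rmsd


def _align_residues(a: Chain, b: Chain) -> List[Tuple[int, int]]:
    """Globally align the two chains' sequences; matched residue index pairs."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a.sequence(), b.sequence())[0]
    pairs: List[Tuple[int, int]] = []
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        pairs.extend((i, j) for i, j in zip(range(s1, e1), range(s2, e2)))
    return pairs


def superpose_on_common(
    model_1: StructuralModel,
    model_2: StructuralModel,
    common_accession: str,
    min_matched: int = 20,
) -> Tuple[StructuralModel, SuperpositionResult]:
    """Superpose ``model_2`` onto ``model_1`` via their shared chain.

    The two common chains are globally sequence-aligned; matched Cα atoms
    drive a Kabsch least-squares fit (>= ``min_matched`` residues
    required). Returns the transformed copy of ``model_2`` and the fit.
    """
    c1 = model_1.chain_for(common_accession)
    c2 = model_2.chain_for(common_accession)
    matched = _align_residues(c2, c1)  # map model_2 onto model_1 frame
    P, Q = [], []
    for i2, i1 in matched:
        ca2, ca1 = c2.residues[i2].ca(), c1.residues[i1].ca()
        if ca2 is not None and ca1 is not None:
            P.append(ca2)
            Q.append(ca1)
    if len(P) < min_matched:
        raise ValueError(
            f"insufficient alignment: {len(P)} matched residues (< {min_matched})"
        )
    R, t, rmsd = _kabsch(np.asarray(P), np.asarray(Q))
    return model_2.transformed(R, t), SuperpositionResult(R, t, rmsd, len(P))


# ---------------------------------------------------------------------------
# Classification


@dataclass
class ExclusivityCall:
    pair: Tuple[str, str]
    common: str
    label: str  # mutually_exclusive | structurally_consistent | inconclusive | excluded
    overlap_interface_residues: int
    overlap_total_residues: int
    rmsd: float
    annotations: Dict = field(default_factory=dict)


def _cross_overlap_count(
    u1: Chain, if1: Set[int], u2: Chain, if2: Set[int], cutoff: float
) -> int:
    """Distinct interface residues of either chain within ``cutoff`` of the
    other chain's interface residues, summed over both chains."""

    def coords_for(chain: Chain, idx: Set[int]):
        coords, ridx = [], []
        for i in sorted(idx):
            for a in chain.residues[i].atoms:
                if not a.is_hydrogen:
                    coords.append(a.xyz)
                    ridx.append(i)
        return np.asarray(coords, dtype=float).reshape(-1, 3), ridx

    x1, r1 = coords_for(u1, if1)
    x2, r2 = coords_for(u2, if2)
    if len(x1) == 0 or len(x2) == 0:
        return 0
    tree = cKDTree(x2)
    close = tree.query_ball_point(x1, cutoff)
    res1 = {r1[i] for i, hits in enumerate(close) if hits}
    res2 = {r2[j] for hits in close for j in hits}
    return len(res1) + len(res2)


def classify_pair(
    model_1: StructuralModel,
    model_2: StructuralModel,
    common_accession: str,
    contact_cutoff: float = 4.0,
    me_min: int = 10,
    sc_clash_max: int = 100,
    superpose: bool = True,
) -> ExclusivityCall:
    """Call a unique-subunit pair mutually exclusive or structurally consistent.

    The models are superposed on the common chain (unless already in a
    shared frame and ``superpose=False``). Each unique chain's interface
    with its own common chain is taken at ``contact_cutoff`` Å between
    heavy atoms; interface residues of the two unique chains closer than
    the cutoff to each other count as overlapping (distinct residues,
    summed over both chains). More than ``me_min`` overlapping interface
    residues → mutually exclusive; exactly 0 → structurally consistent,
    unless the chains overlap anywhere in more than ``sc_clash_max``
    residues (model-clash exclusion); anything in between → inconclusive.
    """
    u1_acc = model_1.other_chain(common_accession).accession
    u2_acc = model_2.other_chain(common_accession).accession
    if u1_acc == u2_acc:
        raise ValueError(f"not a pair: both unique chains are {u1_acc!r}")
    rmsd = 0.0
    if superpose:
        model_2, fit = superpose_on_common(model_1, model_2, common_accession)
        rmsd = fit.rmsd
    u1 = model_1.other_chain(common_accession)
    c1 = model_1.chain_for(common_accession)
    u2 = model_2.other_chain(common_accession)
    c2 = model_2.chain_for(common_accession)

    if1 = interface_residues(u1, c1, contact_cutoff)
    if2 = interface_residues(u2, c2, contact_cutoff)
    overlap_if = _cross_overlap_count(u1, if1, u2, if2, contact_cutoff)
    all1 = set(range(len(u1.residues)))
    all2 = set(range(len(u2.residues)))
    overlap_total = _cross_overlap_count(u1, all1, u2, all2, contact_cutoff)

    if overlap_if > me_min:
        label = "mutually_exclusive"
    elif overlap_if == 0:
        label = "excluded" if overlap_total > sc_clash_max else "structurally_consistent"
    else:
        label = "inconclusive"
    return ExclusivityCall(
        pair=canonical_pair(u1_acc, u2_acc),
        common=common_accession,
        label=label,
        overlap_interface_residues=overlap_if,
        overlap_total_residues=overlap_total,
        rmsd=rmsd,
    )


# ---------------------------------------------------------------------------
# Pair characterization


def annotate_pairs(
    calls: Sequence[ExclusivityCall],
    ortholog_groups: Optional[Mapping[str, str]] = None,
    covariation: Optional[Mapping[Tuple[str, str], float]] = None,
    rna_matrix=None,
    localization: Optional[Mapping[str, Set[str]]] = None,
) -> "pd.DataFrame":
    """Join paralogy, covariation, tissue-correlation and localization onto calls.

    ``rna_matrix`` is a protein x tissue table of nTPM values (pandas
    DataFrame); the tissue-expression similarity is the Pearson r over
    tissues observed for both proteins. Missing lookups yield missing
    annotation fields.
    """
    import pandas as pd

    rows = []
    for call in calls:
        a, b = call.pair
        row = {
            "protein_a": a,
            "protein_b": b,
            "common": call.common,
            "label": call.label,
            "overlap_interface_residues": call.overlap_interface_residues,
            "overlap_total_residues": call.overlap_total_residues,
            "rmsd": call.rmsd,
            "paralog": np.nan,
            "covariation": np.nan,
            "ntpm_pearson": np.nan,
            "localization_jaccard": np.nan,
        }
        if ortholog_groups is not None:
            ga, gb = ortholog_groups.get(a), ortholog_groups.get(b)
            if ga is not None and gb is not None:
                row["paralog"] = bool(ga == gb)
        if covariation is not None:
            row["covariation"] = covariation.get(canonical_pair(a, b), np.nan)
        if rna_matrix is not None and a in rna_matrix.index and b in rna_matrix.index:
            xa, xb = rna_matrix.loc[a], rna_matrix.loc[b]
            mask = xa.notna() & xb.notna()
            if mask.sum() >= 3 and xa[mask].std() > 0 and xb[mask].std() > 0:
                row["ntpm_pearson"] = float(np.corrcoef(xa[mask], xb[mask])[0, 1])
        if localization is not None and a in localization and b in localization:
            la, lb = set(localization[a]), set(localization[b])
            union = la | lb
            row["localization_jaccard"] = len(la & lb) / len(union) if union else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
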