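"""Seeded synthetic fixtures emulating every input of the pipeline.

These generators are first-class, tested code: they plant known structure
(complex memberships, overlapping vs disjoint binding interfaces,
lineage-restricted expression, coherent annotations) and emit truth
tables sufficient to score any downstream result without peeking at
generator internals. Each generator is a pure function of its spec,
seed included; one RNG stream per generator section keeps sections
independent of one another's parameter changes.

The compendium generator emulates bait-prey pulldowns: each experiment
samples one planted complex as bait context, detects its members with a
fixed probability, and sprinkles background preys. It does not model
peptide-level MS noise or batch structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .goldstd import Complex, ComplexSet
from .pairs import Pair, canonical_pair
from .structure import Atom, Chain, Residue, StructuralModel


# ---------------------------------------------------------------------------
# Planted complexes


def plant_complexes(
    n_complexes: int = 20,
    size_range: Tuple[int, int] = (3, 10),
    seed: int = 0,
    prefix: str = "P",
) -> ComplexSet:
    """Disjoint planted complexes with sizes uniform in ``size_range``."""
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    complexes = []
    counter = 0
    for i in range(n_complexes):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(f"{prefix}{counter + j:04d}" for j in range(size))
        counter += size
        complexes.append(Complex(f"planted{i:03d}", members))
    return ComplexSet(complexes)


# ---------------------------------------------------------------------------
# Bait-prey compendium


@dataclass
class CompendiumSpec:
    seed: int
    n_complexes: int = 20
    size_range: Tuple[int, int] = (3, 10)
    n_experiments: int = 200
    detection_prob: float = 0.8
    background_rate: float = 0.05
    n_background_proteins: int = 60
    subthreshold_rate: float = 0.05
    co_pull_prob: float = 0.3
    dataset_tag: str = "sim"

    def __post_init__(self):
        for r in (self.detection_prob, self.background_rate, self.subthreshold_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.n_experiments < 1:
            raise ValueError("zero experiments")


def simulate_compendium(spec: CompendiumSpec) -> Tuple[pd.DataFrame, ComplexSet]:
    """Simulated pulldown observations plus the planted complex truth.

    Returns an observation table (experiment_id, dataset_tag, protein,
    score) in which detected proteins carry scores above 2.0, plus
    sub-threshold noise rows that an abundance filter at 2.0 must drop.

    Besides the bait-context complex, a second complex co-purifies with
    probability ``co_pull_prob`` — as unrelated assemblies routinely do in
    pulldowns — so that non-co-complex protein pairs carry weak but
    non-zero co-occurrence evidence the classifier must learn to discount.
    """
    planted = plant_complexes(spec.n_complexes, spec.size_range, seed=spec.seed)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    background = [f"B{j:04d}" for j in range(spec.n_background_proteins)]
    complexes = planted.complexes
    rows = []
    for e in range(spec.n_experiments):
        eid = f"exp{e:04d}"
        pulled = [complexes[int(rng.integers(len(complexes)))]]
        if rng.random() < spec.co_pull_prob and len(complexes) > 1:
            other = complexes[int(rng.integers(len(complexes)))]
            if other is not pulled[0]:
                pulled.append(other)
        members = sorted(set().union(*(c.members for c in pulled)))
        for p in members:
            if rng.random() < spec.detection_prob:
                rows.append((eid, spec.dataset_tag, p, float(rng.uniform(2.5, 8.0))))
            elif rng.random() < spec.subthreshold_rate:
                rows.append((eid, spec.dataset_tag, p, float(rng.uniform(0.1, 1.9))))
        for b in background:
            if rng.random() < spec.background_rate:
                rows.append((eid, spec.dataset_tag, b, float(rng.uniform(2.5, 8.0))))
    obs = pd.DataFrame(rows, columns=["experiment_id", "dataset_tag", "protein", "score"])
    return obs, planted


# ---------------------------------------------------------------------------
# Dimer geometries


@dataclass
class DimerSpec:
    seed: int
    n_exclusive: int = 50
    n_consistent: int = 50
    common_length: int = 30
    unique_length: int = 12
    ca_spacing: float = 3.8
    dock_distance: float = 3.5  # unique-to-common chain separation, Å
    jitter: float = 0.05

    def __post_init__(self):
        if self.common_length < 20:
            raise ValueError("common chain must allow >= 20 aligned residues")


_CB_OFFSET = np.array([1.4, 0.0, 0.0])  # dummy side-chain atom, along the chain axis


def _chain_from_ca(
    accession: str,
    chain_id: str,
    ca_positions: np.ndarray,
    plddt: np.ndarray,
    rng: np.random.Generator,
    jitter: float,
) -> Chain:
    """A Cα trace with one CB dummy atom per residue and coordinate jitter."""
    residues = []
    for i, ca0 in enumerate(ca_positions):
        ca = ca0 + rng.normal(0, jitter, 3)
        residues.append(
            Residue(
                i + 1,
                "ALA",
                [Atom("CA", "C", ca), Atom("CB", "C", ca + _CB_OFFSET)],
                float(plddt[i]),
            )
        )
    return Chain(accession, chain_id, residues)


def _helical_trace(n_res: int, spacing: float, radius: float = 1.0, turn: float = 1.0) -> np.ndarray:
    """A gently helical Cα trace along x — non-collinear, so a Kabsch fit
    on it has a unique rotation."""
    i = np.arange(n_res)
    return np.column_stack(
        [i * spacing, radius * np.sin(turn * i), radius * np.cos(turn * i)]
    )


def _straight_trace(n_res: int, spacing: float, start: np.ndarray) -> np.ndarray:
    i = np.arange(n_res)[:, None]
    return start + i * np.array([spacing, 0.0, 0.0])


def random_rigid_transform(rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """A uniform random proper rotation (QR-based) and a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20, 20, 3)
    return Q, t


def simulate_dimer_models(
    spec: DimerSpec,
) -> Tuple[List[Tuple[StructuralModel, StructuralModel, str]], pd.DataFrame]:
    """Dimer model pairs with planted overlapping or disjoint interfaces.

    Each instance is two models sharing a common subunit: the common chain
    is a straight Cα trace; the unique chains dock over the same central
    segment (planted mutually exclusive) or on opposite faces (planted
    structurally consistent), at sub-4 Å contact distance. The second
    model of each instance is emitted under a random rigid transform so
    that superposition is always exercised. Returns the model pairs with
    their common accession, and a truth table with quality metadata that
    passes the model filters.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    instances = []
    truth_rows = []
    n_total = spec.n_exclusive + spec.n_consistent
    common_ca = _helical_trace(spec.common_length, spec.ca_spacing)
    dock_start = (spec.common_length - spec.unique_length) // 2
    for i in range(n_total):
        exclusive = i < spec.n_exclusive
        common_acc = f"C{i:03d}"
        acc_a, acc_b = f"U{i:03d}A", f"U{i:03d}B"
        plddt_common = np.clip(rng.normal(85, 3, spec.common_length), 60, 100)
        plddt_a = np.clip(rng.normal(85, 3, spec.unique_length), 60, 100)
        plddt_b = np.clip(rng.normal(85, 3, spec.unique_length), 60, 100)
        # both models carry an identical (up to jitter) helical common trace
        common_1 = _chain_from_ca(
            common_acc, "A", common_ca, plddt_common, rng, spec.jitter
        )
        common_2 = _chain_from_ca(
            common_acc, "A", common_ca, plddt_common, rng, spec.jitter
        )
        start_a = np.array(
            [dock_start * spec.ca_spacing, spec.dock_distance, 0.0]
        )
        chain_a = _chain_from_ca(
            acc_a, "B",
            _straight_trace(spec.unique_length, spec.ca_spacing, start_a),
            plddt_a, rng, spec.jitter,
        )
        if exclusive:
            # same face, nudged in z: interfaces collide after superposition
            start_b = start_a + np.array([0.0, 0.0, 1.0])
        else:
            # opposite face: well beyond contact distance from chain A
            start_b = np.array(
                [dock_start * spec.ca_spacing, -spec.dock_distance, 0.0]
            )
        chain_b = _chain_from_ca(
            acc_b, "B",
            _straight_trace(spec.unique_length, spec.ca_spacing, start_b),
            plddt_b, rng, spec.jitter,
        )
        model_1 = StructuralModel(
            f"{common_acc}__{acc_a}", [common_1, chain_a],
            pdockq=float(rng.uniform(0.3, 0.8)), if_plddt=float(np.mean(plddt_a)),
        )
        model_2 = StructuralModel(
            f"{common_acc}__{acc_b}", [common_2, chain_b],
            pdockq=float(rng.uniform(0.3, 0.8)), if_plddt=float(np.mean(plddt_b)),
        )
        R, t = random_rigid_transform(rng)
        model_2 = model_2.transformed(R, t)
        instances.append((model_1, model_2, common_acc))
        truth_rows.append(
            {
                "protein_a": acc_a,
                "protein_b": acc_b,
                "common": common_acc,
                "planted_label": "mutually_exclusive" if exclusive else "structurally_consistent",
                "pdockq_1": model_1.pdockq,
                "pdockq_2": model_2.pdockq,
                "if_plddt_1": model_1.if_plddt,
                "if_plddt_2": model_2.if_plddt,
            }
        )
    return instances, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Lineage-structured expression


@dataclass
class ExpressionSpec:
    seed: int
    n_lineages: int = 4
    lines_per_lineage: int = 40
    n_exclusive: int = 30
    n_consistent: int = 30
    noise_sd: float = 0.2
    missing_rate: float = 0.1
    n_extra_subunits: int = 3
    homomultimer_fraction: float = 0.0

    def __post_init__(self):
        if self.n_lineages < 2:
            raise ValueError("need >= 2 lineages")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")


def simulate_expression(
    spec: ExpressionSpec,
) -> Tuple[pd.DataFrame, pd.Series, ComplexSet, pd.DataFrame]:
    """Lineage-structured log-abundance matrix with planted pair types.

    Each planted pair lives in its own complex together with
    ``n_extra_subunits`` broadly expressed subunits following the complex's
    lineage-level mean profile. Consistent pairs follow that profile in
    every lineage; exclusive pairs split the lineages in half and are
    entirely unobserved outside their own half, so the two proteins are
    never co-detected. When ``homomultimer_fraction`` > 0, that fraction
    of exclusive pairs is marked as having a homomultimeric common subunit
    and planted with attenuated (soft, anti-correlated rather than
    disjoint) exclusivity.

    Returns (log-abundance matrix, lineage labels, planted complexes,
    truth table with pair labels and common subunits).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    cells = []
    lineage_labels = {}
    for li in range(spec.n_lineages):
        for ci in range(spec.lines_per_lineage):
            cell = f"L{li}_c{ci:03d}"
            cells.append(cell)
            lineage_labels[cell] = f"lineage{li}"
    lineages = pd.Series(lineage_labels)[cells]

    rows: Dict[str, np.ndarray] = {}
    complexes = []
    truth = []
    n_total = spec.n_exclusive + spec.n_consistent
    lineage_of_cell = np.array([int(c.split("_")[0][1:]) for c in cells])
    half = spec.n_lineages // 2
    n_soft = int(round(spec.homomultimer_fraction * spec.n_exclusive))
    for i in range(n_total):
        exclusive = i < spec.n_exclusive
        soft = exclusive and i < n_soft
        a, b = f"X{i:03d}a", f"X{i:03d}b"
        extras = [f"X{i:03d}s{j}" for j in range(spec.n_extra_subunits)]
        members = frozenset([a, b] + extras)
        complexes.append(Complex(f"expcpx{i:03d}", members))
        profile = rng.normal(0.0, 1.0, spec.n_lineages)
        per_cell = profile[lineage_of_cell]
        for s in extras:
            rows[s] = per_cell + rng.normal(0, spec.noise_sd, len(cells))
        if not exclusive:
            rows[a] = per_cell + rng.normal(0, spec.noise_sd, len(cells))
            rows[b] = per_cell + rng.normal(0, spec.noise_sd, len(cells))
        elif soft:
            # multiple equivalent binding sites blunt the exclusivity signal:
            # only mild anti-correlation, both proteins detected everywhere
            rows[a] = per_cell + rng.normal(0, spec.noise_sd, len(cells))
            rows[b] = -0.15 * per_cell + rng.normal(0, 3 * spec.noise_sd, len(cells))
        else:
            va = per_cell + rng.normal(0, spec.noise_sd, len(cells))
            vb = per_cell + rng.normal(0, spec.noise_sd, len(cells))
            va[lineage_of_cell >= half] = np.nan
            vb[lineage_of_cell < half] = np.nan
            rows[a], rows[b] = va, vb
        truth.append(
            {
                "protein_a": a,
                "protein_b": b,
                "planted_label": "exclusive" if exclusive else "consistent",
                "common": extras[0] if extras else "",
                "homomultimer_common": bool(soft),
            }
        )
    matrix = pd.DataFrame(rows, index=cells).T
    if spec.missing_rate > 0:
        mask = rng.random(matrix.shape) < spec.missing_rate
        vals = matrix.to_numpy()
        vals[mask] = np.nan
        matrix = pd.DataFrame(vals, index=matrix.index, columns=matrix.columns)
    return matrix, lineages, ComplexSet(complexes), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Coherent annotations


@dataclass
class AnnotationSpec:
    seed: int
    n_uncharacterized_per_complex: int = 1
    n_extra_term_members: int = 2
    n_background_proteins: int = 60
    uncharacterized_score: int = 3


def simulate_annotations(planted: ComplexSet, spec: AnnotationSpec):
    """Coherent per-complex annotation terms with known transfer truth.

    For each planted complex one term is created covering every member
    except ``n_uncharacterized_per_complex`` proteins, which are marked
    uncharacterized (annotation score <= 3) and stripped of the term.
    A root-flagged decoy covering all proteins is added. Returns
    (AnnotationSets, annotation-score lookup, background set, expected
    transfer rows as a set of (protein, complex_id, term)).
    """
    from .annotate import AnnotationSets, AnnotationTerm

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
    background = sorted(planted.proteins()) + [
        f"BG{j:04d}" for j in range(spec.n_background_proteins)
    ]
    annotations = AnnotationSets()
    scores: Dict[str, int] = {p: 5 for p in background}
    expected: Set[Tuple[str, str, str]] = set()
    for c in sorted(planted, key=lambda c: c.complex_id):
        members = sorted(c.members)
        n_u = min(spec.n_uncharacterized_per_complex, max(len(members) - 2, 0))
        unchar = list(rng.choice(members, size=n_u, replace=False)) if n_u else []
        carriers = [m for m in members if m not in unchar]
        extras = list(
            rng.choice(
                [b for b in background if b.startswith("BG")],
                size=spec.n_extra_term_members,
                replace=False,
            )
        )
        term = f"TERM_{c.complex_id}"
        annotations.add(
            AnnotationTerm(term, "GO", frozenset(carriers + extras), root=False)
        )
        for u in unchar:
            scores[u] = spec.uncharacterized_score
            expected.add((u, c.complex_id, term))
    annotations.add(
        AnnotationTerm("ROOT_TERM", "CORUM", frozenset(background), root=True)
    )
    return annotations, scores, set(background), expected
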