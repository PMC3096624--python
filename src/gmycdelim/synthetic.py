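"""Simulators for trees and alignments with the structure the mixed
Yule-coalescent analysis assumes.

The species process is pure-birth with per-lineage rate lambda1: the
waiting time while j lineages exist is Exp(j*lambda1), and after the
k-th lineage appears the present is placed one further Exp(k*lambda1)
draw later.  Within each species, n sampled tips coalesce with total
rate lambda2*n*(n-1) while n lineages remain; whole subtrees are
rejected and redrawn until the species MRCA is younger than the
species' stem age, preserving the conditional coalescent density the
mixed model assumes.  Sequence evolution is Jukes-Cantor, with optional
diploid heterozygote sites encoded as two-fold IUPAC ambiguity codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import NumericalError, ValidationError
from .seqprep import Alignment
from .trees import Node, UltrametricTree

MAX_REJECTIONS = 100_000

_IUPAC2 = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

SeedLike = Union[int, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SpeciesTree:
    """Pure-birth species tree: root (None when k == 1), species tip
    nodes in label order, their stem ages, and the origin age."""

    root: Optional[Node]
    species_tips: list[Node]
    stem_ages: list[float]
    origin_age: float


def simulate_yule(k: int, lambda1: float, seed: SeedLike = 1) -> SpeciesTree:
    """Grow a pure-birth tree to k tips (heights measured from the
    present, which sits Exp(k*lambda1) after the k-th lineage appears)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if lambda1 <= 0:
        raise ValidationError("lambda1 must be positive")
    rng = _rng(seed)

    t = 0.0
    split_time: dict[int, float] = {}
    first = Node()
    active = [first]
    for j in range(1, k):
        t += rng.exponential(1.0 / (j * lambda1))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        split_time[id(parent)] = t
        for _ in range(2):
            ch = Node(parent=parent)
            parent.children.append(ch)
            active.append(ch)
    t += rng.exponential(1.0 / (k * lambda1))
    present = t

    for i, tip in enumerate(active):
        tip.label = f"S{i + 1}"
        tip.height = 0.0
    root = first if k > 1 else None
    if root is not None:
        for nd in first.preorder():
            if nd.children:
                nd.height = present - split_time[id(nd)]
    stem_ages = [
        (tip.parent.height if tip.parent is not None else present) for tip in active
    ]
    return SpeciesTree(root=root, species_tips=list(active),
                       stem_ages=stem_ages, origin_age=present)


def _simulate_coalescent(
    labels: Sequence[str], lambda2: float, rng: np.random.Generator
) -> Node:
    """Single coalescent genealogy; waiting rate lambda2*n*(n-1) while n
    lineages remain.  Returns the MRCA node (height = MRCA age)."""
    active = [Node(label=lb, height=0.0) for lb in labels]
    t = 0.0
    while len(active) > 1:
        n = len(active)
        t += rng.exponential(1.0 / (lambda2 * n * (n - 1)))
        i, j = sorted(rng.choice(n, size=2, replace=False))
        b = active.pop(int(j))
        a = active.pop(int(i))
        parent = Node(height=t, children=[a, b])
        a.parent = parent
        b.parent = parent
        active.append(parent)
    return active[0]


@dataclass
class SimulationTruth:
    """Generating parameters and the true species partition of a
    simulated mixed tree."""

    lambda1: float
    lambda2: float
    seed: Optional[int]
    partition: dict[str, tuple[str, ...]]
    oldest_mrca: float
    youngest_species_node: Optional[float]

    @property
    def n_species(self) -> int:
        return len(self.partition)

    @property
    def sample_sizes(self) -> dict[str, int]:
        return {sp: len(tips) for sp, tips in self.partition.items()}

    @property
    def true_threshold(self) -> float:
        """Midpoint of the gap between within- and between-species
        branching (the oldest MRCA itself when k == 1)."""
        if self.youngest_species_node is None:
            return self.oldest_mrca
        return 0.5 * (self.oldest_mrca + self.youngest_species_node)


def simulate_mixed_tree(
    k: int,
    lambda1: float,
    n_per_species: Union[int, Sequence[int]],
    lambda2: float,
    seed: SeedLike = 1,
) -> tuple[UltrametricTree, SimulationTruth]:
    """Yule species tree with independent within-species coalescents.

    Within-species genealogies are rejection-sampled until each MRCA is
    younger than the species' stem age (no constraint when k == 1,
    where there is no species boundary); more than
    ``MAX_REJECTIONS`` redraws for one species raises
    :class:`NumericalError` advising a larger lambda2/lambda1
    separation.
    """
    if lambda2 <= 0:
        raise ValidationError("lambda2 must be positive")
    sizes = (
        [int(n_per_species)] * k
        if np.isscalar(n_per_species)
        else [int(v) for v in n_per_species]
    )
    if len(sizes) != k:
        raise ValidationError(f"expected {k} per-species sample sizes, got {len(sizes)}")
    if any(n < 1 for n in sizes):
        raise ValidationError("per-species sample sizes must be >= 1")
    if sum(sizes) < 2:
        raise ValidationError("total sample size must be >= 2")

    rng = _rng(seed)
    sp = simulate_yule(k, lambda1, rng)
    species_node_heights = (
        [nd.height for nd in sp.root.preorder() if nd.children]
        if sp.root is not None else []
    )

    partition: dict[str, tuple[str, ...]] = {}
    mrcas: list[float] = []
    root = sp.root
    for j, (tip, stem, n) in enumerate(zip(sp.species_tips, sp.stem_ages, sizes)):
        species = tip.label
        labels = tuple(f"{species}_{i + 1}" for i in range(n))
        partition[species] = labels
        if n == 1:
            tip.label = labels[0]
            continue
        rejections = 0
        while True:
            sub = _simulate_coalescent(labels, lambda2, rng)
            if k == 1 or sub.height < stem:
                break
            rejections += 1
            if rejections > MAX_REJECTIONS:
                raise NumericalError(
                    f"species {species}: MRCA never fell below its stem age "
                    f"after {MAX_REJECTIONS} redraws; increase the "
                    "lambda2/lambda1 separation"
                )
        mrcas.append(sub.height)
        if tip.parent is None:  # k == 1: the coalescent is the whole tree
            root = sub
        else:
            parent = tip.parent
            parent.children[parent.children.index(tip)] = sub
            sub.parent = parent

    if root is None:  # k == 1 with n == 1 was excluded above
        raise ValidationError("simulation produced no tree")

    truth = SimulationTruth(
        lambda1=lambda1,
        lambda2=lambda2,
        seed=seed if isinstance(seed, int) else None,
        partition=partition,
        oldest_mrca=max(mrcas) if mrcas else 0.0,
        youngest_species_node=(
            min(species_node_heights) if species_node_heights else None
        ),
    )
    return UltrametricTree(root), truth


def simulate_null_tree(n: int, lambda2: float, seed: SeedLike = 1) -> UltrametricTree:
    """Single coalescent genealogy over n contemporaneous tips."""
    if n < 2:
        raise ValidationError("n must be >= 2")
    if lambda2 <= 0:
        raise ValidationError("lambda2 must be positive")
    rng = _rng(seed)
    root = _simulate_coalescent([f"T{i + 1}" for i in range(n)], lambda2, rng)
    return UltrametricTree(root)


def simulate_alignment(
    tree: UltrametricTree,
    bp: int,
    mu: float = 1.0,
    het_rate: float = 0.0,
    seed: SeedLike = 1,
) -> Alignment:
    """Jukes-Cantor evolution along the tree, then heterozygote masking.

    Each site of an equal-frequency root sequence changes along a
    branch of length d with probability (3/4)(1 - exp(-4*mu*d/3)); a
    changed site takes one of the three other bases uniformly.  At the
    tips, each site is independently replaced, with probability
    ``het_rate``, by the two-fold IUPAC code combining it with a
    uniformly chosen distinct base.
    """
    if bp < 1:
        raise ValidationError("bp must be >= 1")
    if mu < 0 or not (0.0 <= het_rate <= 1.0):
        raise ValidationError("mu must be >= 0 and het_rate in [0, 1]")
    rng = _rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    seqs: dict[int, np.ndarray] = {tree.root.index: rng.integers(0, 4, size=bp)}
    names: list[str] = []
    out: dict[str, str] = {}
    for nd in tree.root.preorder():
        if nd is tree.root:
            pass
        else:
            d = nd.parent.height - nd.height
            p_change = 0.75 * (1.0 - np.exp(-4.0 * mu * d / 3.0))
            seq = seqs[nd.parent.index].copy()
            mask = rng.random(bp) < p_change
            n_mut = int(mask.sum())
            if n_mut:
                seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_mut)) % 4
            seqs[nd.index] = seq
        if nd.is_tip:
            seq = seqs[nd.index]
            letters = bases[seq].astype("U1")
            if het_rate > 0:
                hmask = rng.random(bp) < het_rate
                for i in np.nonzero(hmask)[0]:
                    b0 = "ACGT"[seq[i]]
                    b1 = "ACGT"[(seq[i] + rng.integers(1, 4)) % 4]
                    letters[i] = _IUPAC2[frozenset((b0, b1))]
            names.append(nd.label)
            out[nd.label] = "".join(letters)
    return Alignment(names=names, seqs=out)


def truth_to_metadata(truth: SimulationTruth) -> pd.DataFrame:
    """Per-individual metadata table (one population per species)."""
    rows = []
    for sp_name, tips in truth.partition.items():
        for tip in tips:
            rows.append({
                "individual": tip,
                "population": sp_name,
                "nominal_species": sp_name,
                "topotype": 0,
                "species_group": "",
            })
    return pd.DataFrame(rows)


def truth_to_frame(truth: SimulationTruth) -> pd.DataFrame:
    """Flat truth table for TSV export."""
    rows = []
    for sp_name, tips in truth.partition.items():
        rows.append({
            "species": sp_name,
            "n_tips": len(tips),
            "tips": ",".join(tips),
            "lambda1": truth.lambda1,
            "lambda2": truth.lambda2,
            "true_threshold": truth.true_threshold,
            "seed": truth.seed,
        })
    return pd.DataFrame(rows)
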