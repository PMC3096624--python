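"""Mixed Yule-coalescent likelihood, threshold optimization and LR tests.

The model places a boundary on an ultrametric tree between a
diversification (pure-birth) branching process and independent
within-species coalescent processes.  Internal nodes above the boundary
are *diversification* events, nodes below are *coalescent* events; each
lineage crossing the boundary roots a delimited entity (a cluster when
it subtends >= 2 tips, otherwise a singleton).

The likelihood is a product over the inter-event intervals of the tree.
With event heights b_1 > b_2 > ... > b_{n-1} (all internal nodes,
descending) the intervals are [b_1,b_2], ..., [b_{n-1}, 0] and each
contributes ``ln b_i - b_i * x_i`` where ``x_i`` is the interval
duration and ``b_i`` the total branching rate

    b_i = lambda1 * n_div,i**p1 + lambda2 * sum_j (n_ij*(n_ij-1))**p2

``n_div,i`` counts diversification lineages (frozen at the number of
crossing lineages once all diversification events are exhausted) and
``n_ij`` counts lineages of coalescent process j.  The lambda1 term is
dropped when the classification has no diversification node, so the
single-cluster classification reduces exactly to the single-coalescent
null model; the lambda2 term is dropped when there is no cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .errors import NumericalError, ValidationError
from .trees import Node, UltrametricTree, branching_times

log = logging.getLogger(__name__)

#: default half chi-square(1) 95% cutoff for the threshold confidence set
CONFIDENCE_DELTA = 1.92

_LOG_LAM_LO, _LOG_LAM_HI = np.log(1e-12), np.log(1e12)
_P_LO, _P_HI = -5.0, 5.0
_P_STARTS = (0.5, 1.0, 1.5)


# ---------------------------------------------------------------------------
# classification of nodes and entities
# ---------------------------------------------------------------------------

@dataclass
class NodeClassification:
    """Diversification/coalescent labels plus derived entities.

    ``entity_roots`` are the nodes (internal or tip) rooting each
    delimited entity, in preorder; ``coalescent`` holds preorder indices
    of coalescent internal nodes (a tip-ward-closed set).
    """

    tree: UltrametricTree
    entity_roots: list[Node]
    coalescent: frozenset[int]

    @property
    def n_clusters(self) -> int:
        return sum(1 for r in self.entity_roots if not r.is_tip)

    @property
    def n_singletons(self) -> int:
        return sum(1 for r in self.entity_roots if r.is_tip)

    @property
    def n_entities(self) -> int:
        return len(self.entity_roots)

    @property
    def n_diversification(self) -> int:
        return len(self.tree.internal_nodes) - len(self.coalescent)

    def is_coalescent(self, node: Node) -> bool:
        return node.index in self.coalescent

    def roots_key(self) -> frozenset[int]:
        return frozenset(r.index for r in self.entity_roots)

    def youngest_diversification_height(self) -> Optional[float]:
        hs = [nd.height for nd in self.tree.internal_nodes
              if nd.index not in self.coalescent]
        return min(hs) if hs else None

    def local_thresholds(self) -> list[float]:
        """Distinct heights of the diversification nodes directly above
        each entity root (descending)."""
        hs = {r.parent.height for r in self.entity_roots if r.parent is not None}
        return sorted(hs, reverse=True)


def classify_nodes(tree: UltrametricTree, threshold: float) -> NodeClassification:
    """Label nodes by a single threshold height.

    Nodes with height > threshold are diversification; all others are
    coalescent.  Entities are the lineages crossing the threshold.
    """
    if threshold < 0:
        raise ValidationError("threshold must be nonnegative")
    coal = frozenset(
        nd.index for nd in tree.internal_nodes if nd.height <= threshold
    )
    return classification_from_coalescent(tree, coal)


def classification_from_coalescent(
    tree: UltrametricTree, coalescent: frozenset[int]
) -> NodeClassification:
    """Build a classification from the set of coalescent internal nodes."""
    roots: list[Node] = []

    def collect(nd: Node, parent_div: bool) -> None:
        is_coal = nd.is_tip or nd.index in coalescent
        if is_coal and parent_div:
            roots.append(nd)
        if not nd.is_tip and not is_coal:
            for ch in nd.children:
                collect(ch, True)
        elif not nd.is_tip and is_coal:
            for ch in nd.children:
                if not ch.is_tip and ch.index not in coalescent:
                    raise ValidationError(
                        "coalescent nodes must be tip-ward closed"
                    )
                collect(ch, False)

    root_is_coal = tree.root.index in coalescent
    if root_is_coal:
        roots.append(tree.root)
        for ch in tree.root.children:
            collect(ch, False)
    else:
        for ch in tree.root.children:
            collect(ch, True)
    return NodeClassification(tree=tree, entity_roots=roots, coalescent=coalescent)


def classification_from_roots(
    tree: UltrametricTree, root_indices: frozenset[int]
) -> NodeClassification:
    """Build a classification from entity-root node indices."""
    node_by_index = {nd.index: nd for nd in tree.nodes}
    coal = set()
    for idx in root_indices:
        r = node_by_index[idx]
        for nd in r.preorder():
            if not nd.is_tip:
                coal.add(nd.index)
    cls = classification_from_coalescent(tree, frozenset(coal))
    if cls.roots_key() != frozenset(root_indices):
        raise ValidationError("entity roots do not form a valid partition")
    return cls


# ---------------------------------------------------------------------------
# species assignment (shared with the congruence module)
# ---------------------------------------------------------------------------

@dataclass
class Entity:
    """One delimited species: a cluster (>=2 members) or a singleton."""

    entity_id: int
    kind: str  # "cluster" | "singleton"
    members: tuple[str, ...]
    name: Optional[str] = None


@dataclass
class SpeciesAssignment:
    """Disjoint partition of tips (or individuals) into entities."""

    entities: list[Entity]

    def __post_init__(self):
        seen: set[str] = set()
        for e in self.entities:
            for m in e.members:
                if m in seen:
                    raise ValidationError(f"member {m!r} assigned to two entities")
                seen.add(m)

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    def entity_of(self) -> dict[str, Entity]:
        return {m: e for e in self.entities for m in e.members}

    def expand_members(self, mapping: dict[str, Sequence[str]]) -> "SpeciesAssignment":
        """Replace each member by mapping[member] (e.g. haplotype ->
        individuals from a collapse map)."""
        out = []
        for e in self.entities:
            members: list[str] = []
            for m in e.members:
                if m not in mapping:
                    raise ValidationError(f"no mapping for member {m!r}")
                members.extend(mapping[m])
            out.append(Entity(e.entity_id, e.kind, tuple(members), e.name))
        return SpeciesAssignment(out)


def extract_entities(classification: NodeClassification) -> SpeciesAssignment:
    """Entities in deterministic (preorder-of-root) order."""
    entities = []
    for i, r in enumerate(sorted(classification.entity_roots, key=lambda nd: nd.index)):
        members = tuple(t.label for t in r.tips())
        kind = "cluster" if len(members) >= 2 else "singleton"
        entities.append(Entity(entity_id=i + 1, kind=kind, members=members))
    return SpeciesAssignment(entities)


# ---------------------------------------------------------------------------
# interval table (sufficient statistic of the likelihood)
# ---------------------------------------------------------------------------

@dataclass
class IntervalTable:
    """Pooled inter-event waiting times with per-process lineage counts.

    ``qmat[i, k]`` counts coalescent processes whose lineage pair count
    n*(n-1) equals ``qvals[k]`` during interval i (zero pair counts are
    not stored; they contribute nothing).
    """

    x: np.ndarray          # (m,) interval durations, all > 0
    ndiv: np.ndarray       # (m,) diversification lineage counts
    qmat: np.ndarray       # (m, nq) counts of coalescent pair values
    qvals: np.ndarray      # (nq,) distinct n*(n-1) > 0
    has_div: bool
    has_coal: bool
    root_height: float

    @property
    def m(self) -> int:
        return len(self.x)


def build_intervals(classification: NodeClassification) -> IntervalTable:
    """Sweep events from the root to the tips and tabulate counts.

    Events are the internal nodes in descending height order; interval i
    runs from event i down to event i+1 (or to 0 for the last).  The
    diversification lineage count is 1 + number of diversification
    events so far (so it freezes at the number of entities once all
    diversification nodes are passed); coalescent process j counts
    1 + number of its own events so far.
    """
    tree = classification.tree
    events = sorted(tree.internal_nodes, key=lambda nd: -nd.height)
    n_ev = len(events)
    if n_ev == 0:
        raise ValidationError("tree has no internal nodes")

    # map each coalescent internal node to its entity (cluster) id
    cluster_of: dict[int, int] = {}
    clusters = [r for r in classification.entity_roots if not r.is_tip]
    for j, r in enumerate(clusters):
        for nd in r.preorder():
            if not nd.is_tip:
                cluster_of[nd.index] = j

    heights = np.array([nd.height for nd in events])
    ends = np.append(heights[1:], 0.0)
    x = heights - ends
    if np.any(x <= 0):
        raise ValidationError("nonpositive inter-event interval (tied heights?)")

    ndiv = np.empty(n_ev, dtype=np.int64)
    ncl = np.ones(len(clusters), dtype=np.int64)
    d = 1
    qcounts: list[dict[int, int]] = []
    for i, ev in enumerate(events):
        if classification.is_coalescent(ev):
            ncl[cluster_of[ev.index]] += 1
        else:
            d += 1
        ndiv[i] = d
        qrow: dict[int, int] = {}
        for n in ncl:
            q = int(n) * (int(n) - 1)
            if q > 0:
                qrow[q] = qrow.get(q, 0) + 1
        qcounts.append(qrow)

    qvals = sorted({q for row in qcounts for q in row})
    qmat = np.zeros((n_ev, len(qvals)), dtype=np.float64)
    qpos = {q: k for k, q in enumerate(qvals)}
    for i, row in enumerate(qcounts):
        for q, c in row.items():
            qmat[i, qpos[q]] = c

    has_div = classification.n_diversification > 0
    has_coal = bool(qmat.sum() > 0)
    return IntervalTable(
        x=x,
        ndiv=ndiv,
        qmat=qmat,
        qvals=np.asarray(qvals, dtype=np.float64),
        has_div=has_div,
        has_coal=has_coal,
        root_height=tree.root_height,
    )


def null_intervals(tree: UltrametricTree) -> IntervalTable:
    """Interval table of the single-coalescent null classification."""
    return build_intervals(classify_nodes(tree, tree.root_height))


# ---------------------------------------------------------------------------
# log-likelihoods
# ---------------------------------------------------------------------------

def _rates(table: IntervalTable, lam1, p1, lam2, p2):
    b = np.zeros(table.m)
    if table.has_div:
        b = b + lam1 * np.power(table.ndiv.astype(float), p1)
    if table.has_coal:
        b = b + lam2 * (table.qmat @ np.power(table.qvals, p2))
    return b


def _loglik(table: IntervalTable, lam1, p1, lam2, p2) -> float:
    b = _rates(table, lam1, p1, lam2, p2)
    if np.any(b <= 0) or not np.all(np.isfinite(b)):
        return -np.inf
    return float(np.sum(np.log(b)) - np.dot(b, table.x))


def mixed_loglik(
    table: IntervalTable, lam1: float, lam2: float, p1: float, p2: float
) -> float:
    """Mixed-model log-likelihood; reduces to :func:`null_loglik` when
    the classification has no diversification node."""
    if table.m == 0:
        raise ValidationError("empty interval table")
    if (table.has_div and lam1 <= 0) or (table.has_coal and lam2 <= 0):
        raise ValidationError("branching rates must be positive")
    return _loglik(table, lam1, p1, lam2, p2)


def null_loglik(table: IntervalTable, lam: float, p: float) -> float:
    """Single-coalescent null log-likelihood.

    ``table`` must come from the all-coalescent classification (single
    cluster spanning the whole tree).
    """
    if lam <= 0:
        raise ValidationError("rate must be positive")
    if table.has_div:
        raise ValidationError("null model requires a single-cluster table")
    if np.any(table.qmat @ table.qvals < 2):
        raise ValidationError("degenerate interval with fewer than 2 lineages")
    return _loglik(table, 1.0, 0.0, lam, p)


# ---------------------------------------------------------------------------
# rate optimization
# ---------------------------------------------------------------------------

def _pack_mode(table: IntervalTable) -> str:
    if table.has_div and table.has_coal:
        return "both"
    if table.has_div:
        return "div"
    if table.has_coal:
        return "coal"
    raise ValidationError("interval table has neither process active")


def _neg_ll_and_grad(theta, table: IntervalTable, mode: str, fix_p):
    if mode == "both":
        if fix_p is None:
            ll1, p1, ll2, p2 = theta
        else:
            ll1, ll2 = theta
            p1 = p2 = fix_p
    elif mode == "div":
        if fix_p is None:
            ll1, p1 = theta
        else:
            (ll1,) = theta
            p1 = fix_p
        ll2, p2 = 0.0, 0.0
    else:  # coal
        if fix_p is None:
            ll2, p2 = theta
        else:
            (ll2,) = theta
            p2 = fix_p
        ll1, p1 = 0.0, 0.0
    lam1, lam2 = np.exp(ll1), np.exp(ll2)

    a = np.power(table.ndiv.astype(float), p1) if table.has_div else None
    if table.has_coal:
        qp = np.power(table.qvals, p2)
        c = table.qmat @ qp
    else:
        qp = c = None
    b = np.zeros(table.m)
    if a is not None:
        b = b + lam1 * a
    if c is not None:
        b = b + lam2 * c
    if np.any(b <= 0) or not np.all(np.isfinite(b)):
        return np.inf, np.zeros(len(theta))
    ll = np.sum(np.log(b)) - np.dot(b, table.x)
    w = 1.0 / b - table.x  # d logL / d b_i

    grads = []
    if mode in ("both", "div"):
        g_lam1 = lam1 * np.dot(w, a)  # wrt log lam1
        grads.append(g_lam1)
        if fix_p is None:
            la = np.log(table.ndiv.astype(float))
            grads.append(lam1 * np.dot(w, a * la))
    if mode in ("both", "coal"):
        grads.append(lam2 * np.dot(w, c))  # wrt log lam2
        if fix_p is None:
            dc = table.qmat @ (qp * np.log(table.qvals))
            grads.append(lam2 * np.dot(w, dc))
    # packed order matches theta: (log lam1[, p1])(log lam2[, p2])
    return -ll, -np.array(grads)


@dataclass
class RateFit:
    lambda1: float
    p1: float
    lambda2: float
    p2: float
    loglik: float


def fit_rates(table: IntervalTable, fix_p: Optional[float] = None) -> RateFit:
    """Maximize the interval likelihood over the active rate parameters.

    Bounded L-BFGS-B from deterministic multistarts: lambda initialized
    at the analytic p=1 MLEs, p in {0.5, 1, 1.5} (single start at
    ``fix_p`` when p is held fixed).
    """
    mode = _pack_mode(table)
    m = table.m
    # analytic p=1 initializers (event counts per process, floored at 1)
    div_events = int(table.ndiv[-1] - 1)
    coal_events = max(m - div_events, 1)
    lam1_0 = max(div_events, 1) / float(np.dot(table.ndiv, table.x))
    if table.has_coal:
        c1 = table.qmat @ table.qvals
        denom = float(np.dot(c1, table.x))
        lam2_0 = coal_events / denom if denom > 0 else 1.0
    else:
        lam2_0 = 1.0
    ll1_0 = np.clip(np.log(lam1_0), _LOG_LAM_LO, _LOG_LAM_HI)
    ll2_0 = np.clip(np.log(lam2_0), _LOG_LAM_LO, _LOG_LAM_HI)

    p_starts = _P_STARTS if fix_p is None else (fix_p,)
    lam_bound = (_LOG_LAM_LO, _LOG_LAM_HI)
    p_bound = (_P_LO, _P_HI)

    best = None
    for p0 in p_starts:
        if mode == "both":
            x0 = [ll1_0, p0, ll2_0, p0] if fix_p is None else [ll1_0, ll2_0]
            bounds = (
                [lam_bound, p_bound, lam_bound, p_bound]
                if fix_p is None
                else [lam_bound, lam_bound]
            )
        else:
            l0 = ll1_0 if mode == "div" else ll2_0
            x0 = [l0, p0] if fix_p is None else [l0]
            bounds = [lam_bound, p_bound] if fix_p is None else [lam_bound]
        res = minimize(
            _neg_ll_and_grad,
            np.asarray(x0, dtype=float),
            args=(table, mode, fix_p),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise NumericalError("rate optimization failed to converge from any start")

    th = best.x
    if mode == "both":
        if fix_p is None:
            lam1, p1, lam2, p2 = np.exp(th[0]), th[1], np.exp(th[2]), th[3]
        else:
            lam1, lam2 = np.exp(th[0]), np.exp(th[1])
            p1 = p2 = fix_p
    elif mode == "div":
        lam1 = np.exp(th[0])
        p1 = th[1] if fix_p is None else fix_p
        lam2, p2 = float("nan"), float("nan")
    else:
        lam2 = np.exp(th[0])
        p2 = th[1] if fix_p is None else fix_p
        lam1, p1 = float("nan"), float("nan")
    return RateFit(lambda1=lam1, p1=p1, lambda2=lam2, p2=p2, loglik=-best.fun)


# ---------------------------------------------------------------------------
# LR test and confidence set
# ---------------------------------------------------------------------------

def likelihood_ratio_test(
    logL_null: float, logL_alt: float, df: int
) -> tuple[float, float]:
    """LR = 2*(logL_alt - logL_null) clipped at 0; chi-square p-value."""
    if df < 1:
        raise ValidationError("degrees of freedom must be >= 1")
    if logL_alt < logL_null - 1e-6:
        raise ValidationError(
            f"models are not nested: alternative logL {logL_alt:.6f} < "
            f"null logL {logL_null:.6f}"
        )
    lr = max(0.0, 2.0 * (logL_alt - logL_null))
    return lr, float(chi2.sf(lr, df))


def threshold_confidence_set(
    profile: dict[float, float], delta: float = CONFIDENCE_DELTA
) -> list[float]:
    """Candidates whose profile logL is within ``delta`` of the maximum."""
    if not profile:
        raise ValidationError("empty profile")
    best = max(profile.values())
    return sorted(t for t, ll in profile.items() if ll >= best - delta)


# ---------------------------------------------------------------------------
# threshold fitting
# ---------------------------------------------------------------------------

@dataclass
class GmycFit:
    """Result of a GMYC fit (single- or multiple-threshold)."""

    model: str                      # "single" | "multiple"
    lambda1: float
    p1: float
    lambda2: float
    p2: float
    thresholds: list[float]         # reported transition height(s), tip-ward
    logL_mixed: float
    logL_null: float
    null_lambda: float
    null_p: float
    LR: float
    df: int
    p_value: float
    classification: NodeClassification
    assignment: SpeciesAssignment
    profile: Optional[dict[float, float]] = None
    confidence_set: Optional[list[float]] = None
    # for the multiple-threshold model: single-threshold reference logL
    logL_reference: Optional[float] = None
    accepted_moves: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def threshold(self) -> Optional[float]:
        return self.thresholds[0] if self.thresholds else None

    @property
    def n_clusters(self) -> int:
        return self.classification.n_clusters

    @property
    def n_singletons(self) -> int:
        return self.classification.n_singletons

    @property
    def n_species(self) -> int:
        return self.classification.n_entities


def candidate_thresholds(tree: UltrametricTree) -> list[float]:
    """Midpoints between consecutive distinct branching times, plus one
    candidate above the root (the null classification) and one below
    the shallowest node (all singletons); descending order."""
    bt = sorted(set(branching_times(tree)), reverse=True)
    cands = [bt[0] * 1.000001 + 1e-12]
    for a, b in zip(bt, bt[1:]):
        cands.append(0.5 * (a + b))
    cands.append(0.5 * bt[-1])
    return cands


def fit_null(tree: UltrametricTree, fix_p: Optional[float] = None) -> RateFit:
    """Maximize the single-coalescent null model."""
    return fit_rates(null_intervals(tree), fix_p=fix_p)


def fit_single_threshold(
    tree: UltrametricTree,
    df: int = 3,
    delta: float = CONFIDENCE_DELTA,
) -> GmycFit:
    """Profile the mixed likelihood over candidate thresholds.

    At each candidate the four rate parameters are re-optimized; the
    reported threshold T is the height of the youngest diversification
    node of the winning classification (ties in the profile maximum go
    to the candidate delimiting fewer entities).
    """
    if tree.n_tips < 3:
        raise ValidationError("single-threshold fit requires >= 3 tips")
    null_fit = fit_null(tree)

    profile: dict[float, float] = {}
    fits: dict[float, tuple[RateFit, NodeClassification]] = {}
    for cand in candidate_thresholds(tree):
        cls = classify_nodes(tree, cand)
        table = build_intervals(cls)
        rf = fit_rates(table)
        profile[cand] = rf.loglik
        fits[cand] = (rf, cls)
        log.debug("candidate %.8g: logL=%.6f entities=%d", cand, rf.loglik, cls.n_entities)

    best_ll = max(profile.values())
    tied = [c for c, ll in profile.items() if ll >= best_ll - 1e-9]
    best_cand = min(tied, key=lambda c: (fits[c][1].n_entities, -c))
    rf, cls = fits[best_cand]

    lr, pval = likelihood_ratio_test(null_fit.loglik, rf.loglik, df)
    t_best = cls.youngest_diversification_height()
    return GmycFit(
        model="single",
        lambda1=rf.lambda1,
        p1=rf.p1,
        lambda2=rf.lambda2,
        p2=rf.p2,
        thresholds=[t_best] if t_best is not None else [],
        logL_mixed=rf.loglik,
        logL_null=null_fit.loglik,
        null_lambda=null_fit.lambda2,
        null_p=null_fit.p2,
        LR=lr,
        df=df,
        p_value=pval,
        classification=cls,
        assignment=extract_entities(cls),
        profile=profile,
        confidence_set=threshold_confidence_set(profile, delta),
    )


def _neighbor_states(
    tree: UltrametricTree, roots: frozenset[int]
) -> set[frozenset[int]]:
    node_by_index = {nd.index: nd for nd in tree.nodes}
    out: set[frozenset[int]] = set()
    for idx in roots:
        r = node_by_index[idx]
        if not r.is_tip:  # split a cluster at its root
            out.add(roots - {idx} | {ch.index for ch in r.children})
        if r.parent is not None:  # merge with the sister lineage's entities
            p = r.parent
            absorbed = {i for i in roots
                        if _is_descendant_or_self(node_by_index[i], p)}
            out.add(roots - absorbed | {p.index})
    out.discard(roots)
    return out


def _is_descendant_or_self(nd: Node, anc: Node) -> bool:
    while nd is not None:
        if nd is anc:
            return True
        nd = nd.parent
    return False


def fit_multiple_threshold(
    tree: UltrametricTree,
    start: GmycFit,
    df: Optional[int] = None,
) -> GmycFit:
    """Hill-climb over classifications starting from a single-threshold fit.

    Neighbors move each entity boundary one node rootward (merging an
    entity with everything under its parent) or one node tipward
    (splitting a cluster at its root); the best strict improvement is
    accepted until a local maximum.  The LR test compares against the
    single-threshold model; by default df equals the number of accepted
    moves (extra thresholds), floored at 1.
    """
    if start.model != "single":
        raise ValidationError("start must be a single-threshold fit")
    current = start.classification.roots_key()
    cur_rf = RateFit(start.lambda1, start.p1, start.lambda2, start.p2, start.logL_mixed)
    visited = {current}
    moves = 0
    warnings: list[str] = []
    while True:
        best_state, best_rf = None, None
        for state in _neighbor_states(tree, current):
            cls = classification_from_roots(tree, state)
            try:
                rf = fit_rates(build_intervals(cls))
            except NumericalError:
                continue
            if best_rf is None or rf.loglik > best_rf.loglik:
                best_state, best_rf = state, rf
        if best_rf is None or best_rf.loglik <= cur_rf.loglik + 1e-9:
            break
        if best_state in visited:
            warnings.append("cycle detected in hill climb; terminating")
            log.warning(warnings[-1])
            break
        current, cur_rf = best_state, best_rf
        visited.add(current)
        moves += 1

    cls = classification_from_roots(tree, current)
    if df is None:
        df = max(1, moves)
    lr, pval = likelihood_ratio_test(start.logL_mixed, cur_rf.loglik, df)
    return GmycFit(
        model="multiple",
        lambda1=cur_rf.lambda1,
        p1=cur_rf.p1,
        lambda2=cur_rf.lambda2,
        p2=cur_rf.p2,
        thresholds=cls.local_thresholds(),
        logL_mixed=cur_rf.loglik,
        logL_null=start.logL_null,
        null_lambda=start.null_lambda,
        null_p=start.null_p,
        LR=lr,
        df=df,
        p_value=pval,
        classification=cls,
        assignment=extract_entities(cls),
        logL_reference=start.logL_mixed,
        accepted_moves=moves,
        warnings=warnings,
    )
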