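"""Per-branch insertion of query sequences into a fitted reference.

For each placement branch the query is attached via a new node that
splits the branch into a distal and a proximal segment plus a pendant
edge to the query; the three lengths are re-optimized by bounded
coordinate sweeps while every reference conditional-likelihood vector
stays cached (nothing on the reference side is recomputed).  The best
branch is reported; the non-parametric bootstrap resamples alignment
columns and, following the candidate heuristic, re-scores only the top
fraction of branches ranked on the original alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import MAX_BRANCH_LENGTH, MIN_BRANCH_LENGTH, FittedReference
from .alphabet import N_STATES, encode_sequence

_TIE_DECIMALS = 9  # logL ties below 1e-9 are broken by branch id


class QueryError(ValueError):
    pass


@dataclass
class InsertionScore:
    """Result of inserting a query into one placement branch."""

    branch_id: int
    log_likelihood: float
    distal_length: float
    proximal_length: float
    pendant_length: float
    edge_id: int
    edge_distal: float
    rank: int | None = None
    like_weight_ratio: float = 0.0


@dataclass
class PlacementResult:
    query_id: str
    method: str  # "ML" | "MP"
    scores: list[InsertionScore]  # ranked, rank 1 first
    bootstrap_support: dict[int, float] | None = None
    markers: tuple[str, ...] = ()

    @property
    def best(self) -> InsertionScore:
        return self.scores[0]

    def score_for(self, branch_id: int) -> InsertionScore:
        for s in self.scores:
            if s.branch_id == branch_id:
                return s
        raise KeyError(branch_id)

    def reported_placements(self):
        return self.scores


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 100
    candidate_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.candidate_fraction <= 1):
            raise ValueError("candidate fraction must be in (0, 1]")
        if self.n_replicates < 0:
            raise ValueError("replicate count must be >= 0")


def _rank_scores(scores: list[InsertionScore], best_is_max: bool = True) -> list[InsertionScore]:
    sign = -1.0 if best_is_max else 1.0
    ordered = sorted(
        scores, key=lambda s: (sign * round(s.log_likelihood, _TIE_DECIMALS), s.branch_id)
    )
    for i, s in enumerate(ordered):
        s.rank = i + 1
    logls = np.array([s.log_likelihood for s in ordered])
    w = np.exp(logls - logls.max())
    w /= w.sum()
    for s, lw in zip(ordered, w):
        s.like_weight_ratio = float(lw)
    return ordered


class QueryContext:
    """Joint site-pattern compression of (reference pattern, query state).

    Placement likelihood depends on alignment columns only through the
    pair (reference pattern id, query residue); compressing on those
    pairs keeps per-candidate optimization cheap and lets the bootstrap
    reweight patterns instead of rebuilding alignments.
    """

    def __init__(self, fit: FittedReference, query: str | np.ndarray, query_id: str = "query"):
        self.fit = fit
        self.query_id = query_id
        states = encode_sequence(query) if isinstance(query, str) else np.asarray(query)
        n_cols = len(fit.column_map)
        if states.shape[0] != n_cols:
            raise QueryError(
                f"query row has {states.shape[0]} columns, reference has {n_cols}"
            )
        if int((states >= 0).sum()) < 1:
            raise QueryError("query has no informative (non-missing) columns")
        pairs = np.stack([fit.column_map, states.astype(np.int64)], axis=1)
        uniq, inverse, counts = np.unique(
            pairs, axis=0, return_inverse=True, return_counts=True
        )
        self.site_index = uniq[:, 0]  # reference pattern per joint pattern
        self.query_states = uniq[:, 1]
        self.column_to_joint = inverse
        self.base_weights = counts.astype(float)
        qt = np.zeros((len(uniq), N_STATES))
        miss = self.query_states < 0
        qt[np.arange(len(uniq)), np.where(miss, 0, self.query_states)] = 1.0
        qt[miss] = 1.0
        self.query_tip = qt
        self._branch_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _branch_arrays(self, branch_id: int):
        cached = self._branch_cache.get(branch_id)
        if cached is None:
            v = self.fit.branch_child[branch_id]
            A = self.fit.up[v][:, self.site_index, :]
            B = self.fit.down[v][:, self.site_index, :]
            scal = (
                self.fit.up_scaler[v][self.site_index]
                + self.fit.down_scaler[v][self.site_index]
            )
            cached = (A, B, scal)
            self._branch_cache[branch_id] = cached
        return cached

    def insertion_loglik(
        self, branch_id: int, distal: float, pendant: float, weights: np.ndarray | None = None
    ) -> float:
        """logL of the tree with the query attached at (branch, distal, pendant)."""
        fit = self.fit
        w = self.base_weights if weights is None else weights
        A, B, scal = self._branch_arrays(branch_id)
        t = fit.blen[branch_id]
        distal = min(max(distal, 0.0), t)
        model = fit.model
        Pu = model.transition_matrices(t - distal)
        Pd = model.transition_matrices(distal)
        Pp = model.transition_matrices(pendant)
        out = A @ Pu.transpose(0, 2, 1)
        below = B @ Pd.transpose(0, 2, 1)
        qfac = self.query_tip[None, :, :] @ Pp.transpose(0, 2, 1)
        site = np.einsum("kpi,kpi,kpi,i->p", out, below, qfac, model.pi) / model.n_categories
        site = np.maximum(site, 1e-300)
        return float(np.dot(w, np.log(site) + scal))

    # ------------------------------------------------------------------
    def optimize_insertion(
        self,
        branch_id: int,
        weights: np.ndarray | None = None,
        max_rounds: int = 8,
        tol: float = 1e-6,
        init: tuple[float, float] | None = None,
        xatol: float = 1e-6,
    ) -> tuple[float, float, float]:
        """Coordinate optimization of (distal, pendant); returns (logL, d, p).

        Starts from distal = half the branch, pendant = 0.1 unless an
        ``init`` warm start is given (used by bootstrap replicates).
        """
        t = self.fit.blen[branch_id]
        d, p = init if init is not None else (0.5 * t, 0.1)
        best = self.insertion_loglik(branch_id, d, p, weights)
        for _ in range(max_rounds):
            round_start = best
            if t > 2 * MIN_BRANCH_LENGTH:
                res = minimize_scalar(
                    lambda x: -self.insertion_loglik(branch_id, x, p, weights),
                    bounds=(0.0, t),
                    method="bounded",
                    options={"xatol": xatol},
                )
                if -res.fun >= best:
                    d, best = float(res.x), -res.fun
            res = minimize_scalar(
                lambda x: -self.insertion_loglik(branch_id, d, x, weights),
                bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                method="bounded",
                options={"xatol": xatol},
            )
            if -res.fun >= best:
                p, best = float(res.x), -res.fun
            if best - round_start < tol:
                break
        return best, d, p


def score_insertion(
    fit: FittedReference, query, branch_id: int, context: QueryContext | None = None
) -> InsertionScore:
    """Insert the query into one branch, optimizing the three lengths."""
    ctx = context or QueryContext(fit, query)
    branch = fit.branch_by_id[branch_id]
    logl, d, p = ctx.optimize_insertion(branch_id)
    t = fit.blen[branch_id]
    edge_id, edge_distal = branch.to_edge_coordinates(d, fit.tree.edge_lengths())
    return InsertionScore(
        branch_id=branch_id,
        log_likelihood=logl,
        distal_length=d,
        proximal_length=t - d,
        pendant_length=p,
        edge_id=edge_id,
        edge_distal=edge_distal,
    )


def place_query_ml(fit: FittedReference, query, query_id: str = "query") -> PlacementResult:
    """Score every placement branch; rank 1 is the maximum-likelihood branch.

    Ties closer than 1e-9 log units are broken by the smaller branch id.
    """
    ctx = QueryContext(fit, query, query_id)
    scores = [score_insertion(fit, None, b.branch_id, context=ctx) for b in fit.branches]
    return PlacementResult(query_id=query_id, method="ML", scores=_rank_scores(scores))


def select_candidates(result: PlacementResult, fraction: float = 0.10) -> set[int]:
    """Top ``ceil(fraction * B)`` branches of a ranked result (min 1)."""
    n = len(result.scores)
    m = max(1, math.ceil(fraction * n))
    return {s.branch_id for s in result.scores[:m]}


def bootstrap_placements(
    fit: FittedReference,
    query,
    cfg: BootstrapConfig,
    query_id: str = "query",
    full_result: PlacementResult | None = None,
) -> dict[int, float]:
    """Column-resampling bootstrap over the candidate branch set.

    Each replicate resamples post-trim alignment columns with
    replacement (adjusting joint-pattern weights), re-scores only the
    candidate branches, and awards the replicate to the best one.
    Support is the fraction of replicates won; seeded runs are
    reproducible bit for bit.
    """
    if cfg.n_replicates < 1:
        raise ValueError("bootstrap requires at least one replicate")
    ctx = QueryContext(fit, query, query_id)
    if full_result is None:
        scores = [score_insertion(fit, None, b.branch_id, context=ctx) for b in fit.branches]
        full_result = PlacementResult(query_id, "ML", _rank_scores(scores))
    candidates = sorted(select_candidates(full_result, cfg.candidate_fraction))
    warm = {
        s.branch_id: (s.distal_length, s.pendant_length)
        for s in full_result.scores
        if s.branch_id in set(candidates)
    }
    rng = np.random.default_rng(cfg.seed)
    n_cols = len(fit.column_map)
    n_joint = len(ctx.base_weights)
    wins = {b: 0 for b in candidates}
    for _ in range(cfg.n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        w = np.bincount(ctx.column_to_joint[cols], minlength=n_joint).astype(float)
        best_b, best_l = None, -np.inf
        for b in candidates:
            logl, _, _ = ctx.optimize_insertion(
                b, weights=w, init=warm.get(b), max_rounds=3, tol=1e-4, xatol=1e-4
            )
            # candidates iterate in ascending id order, so ties within
            # 1e-9 keep the smaller branch id
            if logl > best_l + 1e-9:
                best_b, best_l = b, logl
        wins[best_b] += 1
    return {b: wins[b] / cfg.n_replicates for b in candidates}


def place_batch(fit: FittedReference, queries: dict[str, str], method: str = "ML", tree=None, msa=None):
    """Place a batch of aligned queries; failures are collected, not fatal.

    Results are independent of batch order and partitioning, so runs
    may be split and the outputs concatenated.
    """
    from .parsimony import place_query_mp

    results: list[PlacementResult] = []
    errors: dict[str, str] = {}
    for qid, row in queries.items():
        try:
            if method.upper() == "ML":
                results.append(place_query_ml(fit, row, qid))
            elif method.upper() == "MP":
                results.append(place_query_mp(fit.tree, fit.msa, row, qid))
            else:
                raise QueryError(f"unknown method {method!r}")
        except QueryError as exc:
            errors[qid] = str(exc)
    return results, errors
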