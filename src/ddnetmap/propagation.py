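"""Random-walk-with-restart propagation and Network Proximity Scores.

Heat is spread from a set of seed genes over the network.  With restart
probability ``1 - alpha`` the walker jumps back to a seed; the stationary
heat distribution has the closed form

    F = (I - alpha * W)^{-1} (1 - alpha) * Y0

where ``W`` is the column-stochastic transition matrix and ``Y0`` puts
uniform mass ``1/|seeds|`` on the seed genes.  Because ``W`` is column
stochastic the total heat is conserved: ``sum(F) == sum(Y0) == 1``.

Observed heats are calibrated against an ensemble of random seed sets
that preserve the size and degree distribution of the real seed set.
The Network Proximity Score of gene *g* is the z-score of its log
observed heat against the log heats it receives from the null ensemble:

    NPS_g = (log F_g - mean(log F_g,rand)) / sd(log F_g,rand)

Genes with NPS above a threshold (default 3) are called seed-proximal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ParameterError
from .network import GeneNetwork

__all__ = [
    "PropagationConfig",
    "NetworkPropagation",
    "PropagationResults",
    "seed_vector",
    "propagate",
    "propagate_power_iteration",
    "sample_degree_matched_sets",
    "compute_nps",
    "filter_nps",
]


@dataclass
class PropagationConfig:
    """Propagation and null-calibration settings.

    alpha : float
        Heat retention rate in (0, 1); restart mass is ``1 - alpha``.
    n_null : int
        Number of degree-matched random seed sets in the null ensemble.
    nps_threshold : float
        Strict lower bound for calling a gene seed-proximal.
    degree_bins : int
        Number of equal-width bins in log10(degree + 1) used for
        degree-matched null sampling.
    rng_seed : int
        Seed governing all null-set sampling.
    solver_tol : float
        Residual tolerance asserted on the direct linear solve.
    """

    alpha: float = 0.5
    n_null: int = 100
    nps_threshold: float = 3.0
    degree_bins: int = 10
    rng_seed: int = 0
    solver_tol: float = 1e-10

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_null < 2:
            raise ParameterError("n_null must be >= 2")
        if self.degree_bins < 1:
            raise ParameterError("degree_bins must be >= 1")


def seed_vector(network: GeneNetwork, seed_genes) -> tuple[np.ndarray, list[str], list[str]]:
    """Uniform-mass seed vector; seeds absent from the network are dropped.

    Returns ``(y0, kept_seeds, dropped_seeds)`` with ``sum(y0) == 1``.
    """
    seed_genes = list(dict.fromkeys(seed_genes))
    kept = [g for g in seed_genes if g in network]
    dropped = [g for g in seed_genes if g not in network]
    if not kept:
        raise ParameterError("no seed genes present in the network")
    y0 = np.zeros(network.n_genes)
    y0[[network.index(g) for g in kept]] = 1.0 / len(kept)
    return y0, kept, dropped


def propagate(network: GeneNetwork, y0: np.ndarray, alpha: float,
              solver=None, solver_tol: float = 1e-10) -> np.ndarray:
    """Solve ``(I - alpha W) F = (1 - alpha) Y0`` directly.

    ``solver`` may be a prefactorized :func:`scipy.sparse.linalg.splu`
    object for ``I - alpha W`` to amortize the factorization over the
    null ensemble.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0,1), got {alpha}")
    if np.sum(y0) <= 0:
        raise ParameterError("empty seed vector")
    rhs = (1.0 - alpha) * y0
    if solver is None:
        solver = _factorize(network, alpha)
    F = solver.solve(rhs)
    A = sp.identity(network.n_genes, format="csc") - alpha * network.W
    resid = np.max(np.abs(A @ F - rhs))
    if resid > solver_tol:
        raise ParameterError(f"linear solve residual {resid:.2e} exceeds tol")
    return F


def _factorize(network: GeneNetwork, alpha: float):
    A = sp.identity(network.n_genes, format="csc") - alpha * network.W
    return spla.splu(sp.csc_matrix(A))


def propagate_power_iteration(network: GeneNetwork, y0: np.ndarray, alpha: float,
                              tol: float = 1e-12, max_iter: int = 100000) -> np.ndarray:
    """Fixed-point iteration ``F <- (1-alpha) Y0 + alpha W F``.

    Converges geometrically for ``alpha < 1``; serves as the independent
    oracle for :func:`propagate`.
    """
    if np.sum(y0) <= 0:
        raise ParameterError("empty seed vector")
    W = network.W
    base = (1.0 - alpha) * y0
    F = y0.copy()
    for _ in range(max_iter):
        F_new = base + alpha * (W @ F)
        if np.max(np.abs(F_new - F)) < tol:
            return F_new
        F = F_new
    raise ParameterError("power iteration did not converge")  # unreachable for alpha<1


# ----------------------------------------------------------------------
# degree-matched null sampling
# ----------------------------------------------------------------------

def _degree_bin_members(network: GeneNetwork, n_bins: int):
    """Assign every gene to an equal-width bin in log10(degree+1).

    Bins holding fewer than 2 genes are merged with the nearest nonempty
    neighbour so every draw has at least one alternative.  Returns
    ``(bin_of_gene_index, members_by_bin, n_merged)``.
    """
    deg = network.degrees()
    logd = np.log10(deg + 1.0)
    lo, hi = logd.min(), logd.max()
    if hi == lo:
        edges = np.array([lo, hi + 1.0])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.digitize(logd, edges[1:-1]), 0, len(edges) - 2)
    members = {b: np.flatnonzero(bins == b) for b in range(len(edges) - 1)}
    members = {b: m for b, m in members.items() if m.size}
    # merge undersized bins into the nearest neighbour by bin index
    n_merged = 0
    changed = True
    while changed and len(members) > 1:
        changed = False
        for b in sorted(members):
            if members[b].size < 2:
                others = [o for o in members if o != b]
                nearest = min(others, key=lambda o: abs(o - b))
                members[nearest] = np.concatenate([members[nearest], members[b]])
                del members[b]
                n_merged += 1
                changed = True
                break
    bin_of = np.empty(network.n_genes, dtype=int)
    for b, m in members.items():
        bin_of[m] = b
    members = {b: np.sort(m) for b, m in members.items()}
    return bin_of, members, n_merged


def sample_degree_matched_sets(network: GeneNetwork, seed_set, n_null: int,
                               degree_bins: int = 10, rng_seed: int = 0) -> list[list[str]]:
    """Draw ``n_null`` random gene sets matching the seed set's size and
    degree distribution.

    Each seed gene is replaced by a uniform draw (without replacement
    within a set) from its log10-degree bin.  A null set may contain
    original seed genes but never reproduces the exact seed set.
    """
    seed_set = list(dict.fromkeys(seed_set))
    seed_idx = [network.index(g) for g in seed_set]
    bin_of, members, _ = _degree_bin_members(network, degree_bins)
    rng = np.random.default_rng(rng_seed)
    seed_frozen = frozenset(seed_idx)
    sets: list[list[str]] = []
    for _ in range(n_null):
        for _attempt in range(1000):
            chosen: list[int] = []
            taken: set[int] = set()
            ok = True
            for si in seed_idx:
                pool = members[bin_of[si]]
                avail = pool[~np.isin(pool, list(taken))] if taken else pool
                if avail.size == 0:
                    ok = False
                    break
                pick = int(rng.choice(avail))
                chosen.append(pick)
                taken.add(pick)
            if ok and frozenset(chosen) != seed_frozen:
                sets.append([network.genes[i] for i in chosen])
                break
        else:
            raise ParameterError("could not sample a degree-matched set distinct "
                                 "from the seed set")
    return sets


# ----------------------------------------------------------------------
# NPS
# ----------------------------------------------------------------------

def compute_nps(F_obs: np.ndarray, null_heats: np.ndarray, genes,
                restrict_to_positive: bool = True) -> pd.DataFrame:
    """Z-score log observed heat against the log null-heat ensemble.

    Genes with any non-positive heat (observed or in any null run) cannot
    be log-transformed and are excluded from scoring with flag
    ``zero_heat``; genes whose null log-heats are constant get flag
    ``degenerate_null``.  The null standard deviation is the population
    formula (ddof=0).
    """
    null_heats = np.asarray(null_heats, dtype=float)
    if null_heats.ndim != 2 or null_heats.shape[0] < 2:
        raise ParameterError("null_heats must be an (n_null, n_genes) matrix with n_null >= 2")
    F_obs = np.asarray(F_obs, dtype=float)
    n = F_obs.size
    flags = np.array([""] * n, dtype=object)
    scorable = np.ones(n, dtype=bool)
    if restrict_to_positive:
        zero = (F_obs <= 0) | np.any(null_heats <= 0, axis=0)
        flags[zero] = "zero_heat"
        scorable &= ~zero
    log_obs = np.full(n, np.nan)
    log_obs[scorable] = np.log(F_obs[scorable])
    mu = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    log_null_sc = np.log(null_heats[:, scorable])
    mu[scorable] = log_null_sc.mean(axis=0)
    sd[scorable] = log_null_sc.std(axis=0, ddof=0)
    degenerate = scorable & (sd == 0)
    flags[degenerate] = "degenerate_null"
    scorable &= ~degenerate
    nps = np.full(n, np.nan)
    nps[scorable] = (log_obs[scorable] - mu[scorable]) / sd[scorable]
    return pd.DataFrame({
        "gene": list(genes),
        "heat": F_obs,
        "null_log_mean": np.where(~np.isnan(mu), mu, np.nan),
        "null_log_sd": sd,
        "nps": nps,
        "flags": flags,
    })


def filter_nps(nps_table: pd.DataFrame, threshold: float = 3.0) -> list[str]:
    """Genes with NPS strictly above ``threshold``."""
    mask = nps_table["nps"] > threshold
    return nps_table.loc[mask, "gene"].tolist()


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------

class NetworkPropagation:
    """Propagation model: a network, a seed gene set and a config.

    ``fit()`` runs the observed propagation, samples the degree-matched
    null ensemble, propagates every null set reusing one matrix
    factorization, and returns :class:`PropagationResults`.
    """

    def __init__(self, network: GeneNetwork, seed_genes, config: PropagationConfig | None = None):
        self.network = network
        self.config = config or PropagationConfig()
        self.y0, self.seed_genes, self.dropped_seeds = seed_vector(network, seed_genes)

    def fit(self) -> "PropagationResults":
        cfg = self.config
        solver = _factorize(self.network, cfg.alpha)
        F_obs = propagate(self.network, self.y0, cfg.alpha, solver=solver,
                          solver_tol=cfg.solver_tol)
        null_sets = sample_degree_matched_sets(
            self.network, self.seed_genes, cfg.n_null,
            degree_bins=cfg.degree_bins, rng_seed=cfg.rng_seed)
        null_heats = np.empty((cfg.n_null, self.network.n_genes))
        for k, gene_set in enumerate(null_sets):
            y0k, _, _ = seed_vector(self.network, gene_set)
            null_heats[k] = propagate(self.network, y0k, cfg.alpha, solver=solver,
                                      solver_tol=cfg.solver_tol)
        nps = compute_nps(F_obs, null_heats, self.network.genes)
        nps["selected"] = (nps["nps"] > cfg.nps_threshold).fillna(False)
        nps["is_seed"] = nps["gene"].isin(self.seed_genes)
        return PropagationResults(self, F_obs, null_heats, null_sets, nps)


@dataclass
class PropagationResults:
    """Observed heats, the null ensemble and per-gene NPS records."""

    model: NetworkPropagation
    F_obs: np.ndarray
    null_heats: np.ndarray
    null_sets: list = field(repr=False, default_factory=list)
    nps: pd.DataFrame = None

    def selected(self, threshold: float | None = None, exclude_seeds: bool = False) -> list[str]:
        thr = self.model.config.nps_threshold if threshold is None else threshold
        out = filter_nps(self.nps, thr)
        if exclude_seeds:
            out = [g for g in out if g not in set(self.model.seed_genes)]
        return out

    def to_tsv(self, path) -> None:
        cols = ["gene", "heat", "null_log_mean", "null_log_sd", "nps", "selected", "flags"]
        df = self.nps[cols].copy()
        for c in ("heat", "null_log_mean", "null_log_sd", "nps"):
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.10g}")
        df.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        cfg = self.model.config
        nsel = int(self.nps["selected"].sum())
        nzero = int((self.nps["flags"] == "zero_heat").sum())
        top = self.nps.sort_values("nps", ascending=False).head(10)
        lines = [
            "Network propagation results",
            "===========================",
            f"genes: {self.model.network.n_genes}   edges: {self.model.network.n_edges}",
            f"seeds: {len(self.model.seed_genes)} (dropped: {len(self.model.dropped_seeds)})",
            f"alpha: {cfg.alpha}   n_null: {cfg.n_null}   NPS threshold: {cfg.nps_threshold}",
            f"heat conserved: sum(F) = {self.F_obs.sum():.12f}",
            f"selected (NPS > {cfg.nps_threshold}): {nsel}   zero-heat excluded: {nzero}",
            "",
            "top genes by NPS:",
        ]
        for _, r in top.iterrows():
            lines.append(f"  {r['gene']:<12} heat={r['heat']:.3e}  nps={r['nps']:.3f}"
                         f"{'  [seed]' if r['is_seed'] else ''}")
        return "\n".join(lines)
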