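"""Synthetic benchmark data with known ground truth.

Three generators cover the inputs the pipeline consumes:

* a planted-partition (stochastic block model) gene network with
  tunable within/between-community edge densities and positive edge
  weights — the minimal model with community structure and degree
  heterogeneity;
* seed and trait gene-sets concentrated in chosen planted communities
  to a controllable degree (purity / overlap fractions);
* questionnaire choice profiles generated from a known discounting rate
  k under a logistic (softmax) choice rule, with temperature 0 giving a
  perfectly consistent deterministic chooser.

All generators are deterministic given their integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .mcq import MISSING, ChoiceProfile, MCQItem, default_item_bank
from .network import GeneNetwork

__all__ = [
    "PlantedNetworkSpec",
    "PlantedNetwork",
    "ChoiceSimSpec",
    "gen_network",
    "gen_seed_set",
    "gen_trait_sets",
    "gen_mcq_responses",
    "gen_cohort",
]


@dataclass
class PlantedNetworkSpec:
    """Stochastic-block-model parameters for a planted gene network."""

    n_genes: int = 200
    n_communities: int = 4
    p_within: float = 0.15
    p_between: float = 0.01
    weight_range: tuple[float, float] = (0.5, 1.0)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_communities < 1 or self.n_genes < self.n_communities:
            raise ParameterError("need n_genes >= n_communities >= 1")
        if not (0 <= self.p_between < self.p_within <= 1):
            raise ParameterError("need 0 <= p_between < p_within <= 1")
        lo, hi = self.weight_range
        if not (0 < lo <= hi):
            raise ParameterError("weight_range must be positive with min <= max")


@dataclass
class PlantedNetwork:
    """A generated network together with its planted community labels.

    ``membership`` maps every generated gene (including any that ended up
    isolated and were therefore dropped from the network) to its planted
    community index.
    """

    network: GeneNetwork
    membership: dict[str, int]
    spec: PlantedNetworkSpec

    def community_members(self, community_id: int, in_network_only: bool = True) -> list[str]:
        out = [g for g, c in self.membership.items() if c == community_id]
        if in_network_only:
            out = [g for g in out if g in self.network]
        return sorted(out)


def _gene_name(i: int, n: int) -> str:
    width = max(4, len(str(n - 1)))
    return f"G{i:0{width}d}"


def gen_network(spec: PlantedNetworkSpec) -> PlantedNetwork:
    """Sample a planted-partition network.

    Genes are split into ``n_communities`` contiguous near-equal blocks;
    each within-block pair is joined with probability ``p_within`` and
    each between-block pair with ``p_between``; weights are uniform in
    ``weight_range``.  Genes left with no edge are excluded from the
    returned network (but kept in the membership map).
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, k = spec.n_genes, spec.n_communities
    base, extra = divmod(n, k)
    labels = np.repeat(np.arange(k), [base + (1 if c < extra else 0) for c in range(k)])
    genes = [_gene_name(i, n) for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(same, spec.p_within, spec.p_between)
    keep = rng.random(p.size) < p
    lo, hi = spec.weight_range
    weights = rng.uniform(lo, hi, size=int(keep.sum()))
    edges = [
        (genes[i], genes[j], float(w))
        for i, j, w in zip(iu[keep], ju[keep], weights)
    ]
    if not edges:
        raise ParameterError("generated network has no edges; raise densities")
    net = GeneNetwork(edges)
    net.report.isolated_genes_dropped = n - net.n_genes
    return PlantedNetwork(net, dict(zip(genes, labels.tolist())), spec)


def gen_seed_set(planted: PlantedNetwork, community_id: int, size: int,
                 purity: float = 1.0, rng_seed: int = 0) -> list[str]:
    """Sample a seed gene-set concentrated in one planted community.

    ``ceil(purity * size)`` genes come from the target community and the
    remainder from the rest of the network; no duplicates.
    """
    if not 0 <= purity <= 1:
        raise ParameterError("purity must be in [0, 1]")
    if size > planted.network.n_genes:
        raise ParameterError("seed set larger than the network")
    n_in = math.ceil(purity * size)
    members = planted.community_members(community_id)
    if n_in > len(members):
        raise ParameterError(
            f"community {community_id} has {len(members)} network genes, "
            f"need {n_in}")
    others = sorted(set(planted.network.genes) - set(members))
    if size - n_in > len(others):
        raise ParameterError("not enough out-of-community genes")
    rng = np.random.default_rng(rng_seed)
    chosen = list(rng.choice(members, size=n_in, replace=False)) + \
        list(rng.choice(others, size=size - n_in, replace=False))
    return sorted(chosen)


def gen_trait_sets(planted: PlantedNetwork, overlap_matrix: pd.DataFrame,
                   sizes: dict[str, int], rng_seed: int = 0) -> dict[str, frozenset]:
    """Sample named trait gene-sets with controlled community overlap.

    ``overlap_matrix`` is traits x planted-community-ids with entries in
    [0, 1]: the fraction of each trait set drawn from that community
    (exact counts, rounded).  Row sums must not exceed 1; any remainder
    is drawn uniformly from genes outside every community the trait
    requested a positive fraction from, so requested overlaps are exact.
    """
    rng = np.random.default_rng(rng_seed)
    out: dict[str, frozenset] = {}
    if ((overlap_matrix < 0) | (overlap_matrix > 1)).any().any():
        raise ParameterError("overlap fractions must lie in [0, 1]")
    for trait in overlap_matrix.index:
        size = sizes[trait]
        fracs = overlap_matrix.loc[trait]
        if fracs.sum() > 1 + 1e-9:
            raise ParameterError(f"trait {trait}: overlap fractions sum to > 1")
        chosen: list[str] = []
        for comm in overlap_matrix.columns:
            n_c = round(float(fracs[comm]) * size)
            if n_c == 0:
                continue
            pool = sorted(set(planted.community_members(int(comm))) - set(chosen))
            if n_c > len(pool):
                raise ParameterError(
                    f"trait {trait}: community {comm} cannot supply {n_c} genes")
            chosen += list(rng.choice(pool, size=n_c, replace=False))
        rest = size - len(chosen)
        constrained: set[str] = set()
        for comm in overlap_matrix.columns:
            if float(fracs[comm]) > 0:
                constrained |= set(planted.community_members(int(comm)))
        pool = sorted(set(planted.network.genes) - set(chosen) - constrained)
        if rest > len(pool):
            raise ParameterError(f"trait {trait}: network too small for size {size}")
        if rest > 0:
            chosen += list(rng.choice(pool, size=rest, replace=False))
        out[str(trait)] = frozenset(chosen)
    return out


# ----------------------------------------------------------------------
# choice simulation
# ----------------------------------------------------------------------

@dataclass
class ChoiceSimSpec:
    """A simulated questionnaire respondent with known log10(k)."""

    true_log10_k: float
    noise_temperature: float = 0.0
    items: list[MCQItem] = field(default_factory=default_item_bank)
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_temperature < 0:
            raise ParameterError("noise_temperature must be >= 0")
        if not self.items:
            raise ParameterError("item bank must be nonempty")


def gen_mcq_responses(spec: ChoiceSimSpec, participant_id: str = "sim") -> ChoiceProfile:
    """Simulate one choice profile from a known discounting rate.

    The delayed option's hyperbolic value is ``A_del / (1 + k D)``; the
    probability of choosing it is logistic in the value difference
    scaled by the noise temperature.  Temperature 0 is the deterministic
    argmax chooser, with exact value ties resolved to "delayed".
    """
    k = 10.0 ** spec.true_log10_k
    rng = np.random.default_rng(spec.rng_seed)
    choices = []
    for item in spec.items:
        v_del = item.delayed_amount / (1.0 + k * item.delay_days)
        v_imm = item.immediate_amount
        if spec.noise_temperature == 0:
            choices.append(1 if v_del >= v_imm else 0)
        else:
            p_del = 1.0 / (1.0 + np.exp(-(v_del - v_imm) / spec.noise_temperature))
            choices.append(int(rng.random() < p_del))
    return ChoiceProfile(participant_id, choices)


def gen_cohort(true_log10_ks, noise_temperature: float = 0.0,
               items=None, rng_seed: int = 0) -> pd.DataFrame:
    """Choice matrix (participant_id + one 0/1 column per item) for a
    cohort of simulated respondents with the given true log10(k)s."""
    items = list(items) if items is not None else default_item_bank()
    rows = []
    for i, lk in enumerate(true_log10_ks):
        prof = gen_mcq_responses(
            ChoiceSimSpec(float(lk), noise_temperature, items,
                          rng_seed=rng_seed + i),
            participant_id=f"P{i:04d}")
        row = {"participant_id": prof.participant_id}
        for it, c in zip(items, prof.choices):
            row[f"item_{it.item_id}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
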