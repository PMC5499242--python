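"""Synthetic connectome and cohort generator.

Emulates an 83-region weighted, undirected structural connectome:
modular topology (stronger within-module than between-module wiring),
heavy-tailed positive streamline counts, FA values inside (0, 1), a set
of planted high-strength hub regions with extra inter-module edges, and
a three-group cohort design in which hub-incident weights are attenuated
(patients < siblings < healthy).  Everything is reproducible from a
single integer seed; subsidiary generators are derived from it by fixed
stream offsets so each component can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .matrices import ConnectivityMatrix, MatrixRole
from .fusion import build_nosfa

__all__ = ["SimulationConfig", "Cohort", "simulate_connectome", "simulate_cohort"]

# fixed offsets for deriving independent substreams from the master seed
_STREAM_TOPOLOGY = 0
_STREAM_WEIGHTS = 1
_STREAM_FA = 2
_STREAM_SUBJECTS = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the 83-region parcellation with 15 hubs and the
    three-group schizophrenia design (60 healthy / 83 siblings / 62
    patients, healthy > siblings > patients in hub-incident weight).
    """

    n_regions: int = 83
    n_modules: int = 6
    p_intra: float = 0.6
    p_inter: float = 0.15
    p_hub_hub: float = 0.9   # rich-club wiring density among hubs
    n_hubs: int = 15
    hub_strength_multiplier: float = 3.0
    nos_mu: float = 3.0          # log-normal location of streamline counts
    nos_sigma: float = 1.0       # log-normal scale (heavy tail)
    fa_alpha: float = 4.0        # Beta shape parameters for FA
    fa_beta: float = 2.0
    fa_min: float = 0.2
    fa_max: float = 0.8
    fa_nos_correlation: float = 0.0  # 0 = independent; >0 blends FA toward NoS rank
    group_effects: Mapping[str, float] = field(
        default_factory=lambda: {"healthy": 1.0, "siblings": 0.95, "patients": 0.90}
    )
    n_subjects: Mapping[str, int] = field(
        default_factory=lambda: {"healthy": 60, "siblings": 83, "patients": 62}
    )
    subject_noise_sigma: float = 0.1  # log-normal sd of per-subject weight noise

    def validate(self) -> None:
        if self.n_hubs > self.n_regions:
            raise ValueError("n_hubs cannot exceed n_regions")
        if self.n_modules < 1 or self.n_modules > self.n_regions:
            raise ValueError("n_modules must be in [1, n_regions]")
        for p in (self.p_intra, self.p_inter, self.p_hub_hub):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must lie in [0, 1]")
        if not 0.0 < self.fa_min < self.fa_max < 1.0:
            raise ValueError("FA range must satisfy 0 < fa_min < fa_max < 1")
        for label, a in self.group_effects.items():
            if not 0.0 < a <= 1.0:
                raise ValueError(f"attenuation for {label!r} must lie in (0, 1]")


@dataclass(frozen=True)
class Cohort:
    """A simulated multi-group cohort of NoS/FA matrix pairs."""

    manifest: pd.DataFrame  # columns: subject_id, group
    matrices: dict[str, tuple[ConnectivityMatrix, ConnectivityMatrix]]
    planted_hubs: tuple[int, ...]
    base_nos: ConnectivityMatrix
    base_fa: ConnectivityMatrix

    def fused(self) -> dict[str, list[ConnectivityMatrix]]:
        """Group label -> list of fused NoS-FA matrices, study-ready."""
        out: dict[str, list[ConnectivityMatrix]] = {}
        for _, row in self.manifest.iterrows():
            nos, fa = self.matrices[row["subject_id"]]
            out.setdefault(row["group"], []).append(build_nosfa(nos, fa))
        return out


def _modules(cfg: SimulationConfig) -> np.ndarray:
    """Contiguous, near-equal module assignment per region."""
    return np.sort(np.arange(cfg.n_regions) % cfg.n_modules)


def _plant_hubs(cfg: SimulationConfig, module_of: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pick hubs spread across modules (round-robin over modules)."""
    hubs: list[int] = []
    pools = [list(np.flatnonzero(module_of == m)) for m in range(cfg.n_modules)]
    for pool in pools:
        rng.shuffle(pool)
    m = 0
    while len(hubs) < cfg.n_hubs:
        if pools[m % cfg.n_modules]:
            hubs.append(pools[m % cfg.n_modules].pop())
        m += 1
    return np.sort(np.array(hubs, dtype=int))


def _topology(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric 0/1 adjacency with modular structure and hub wiring.

    Connectivity is guaranteed by overlaying a uniformly random spanning
    tree.  Hub regions receive inter-module edges at the intra-module
    probability (high degree) and are densely wired to each other at
    ``p_hub_hub`` — the rich-club organization characteristic of real
    connectome hubs.
    """
    n = cfg.n_regions
    module_of = _modules(cfg)
    hubs = _plant_hubs(cfg, module_of, rng)
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True

    same = module_of[:, None] == module_of[None, :]
    hub_pair = is_hub[:, None] | is_hub[None, :]
    both_hub = is_hub[:, None] & is_hub[None, :]
    p = np.where(same, cfg.p_intra, np.where(hub_pair, cfg.p_intra, cfg.p_inter))
    p = np.where(both_hub, cfg.p_hub_hub, p)
    upper = np.triu(rng.random((n, n)) < p, k=1)

    # random spanning tree: shuffled order, each node attaches to a random predecessor
    order = rng.permutation(n)
    for k in range(1, n):
        a, b = order[k], order[rng.integers(0, k)]
        i, j = (a, b) if a < b else (b, a)
        upper[i, j] = True

    adj = upper | upper.T
    return adj.astype(int), hubs


def simulate_connectome(
    cfg: SimulationConfig, seed: int
) -> tuple[ConnectivityMatrix, ConnectivityMatrix, tuple[int, ...]]:
    """Generate one (NoS, FA) matrix pair with planted hubs.

    Returns the NoS matrix (integer-rounded log-normal weights,
    multiplied by ``hub_strength_multiplier`` once per hub endpoint of
    each edge), the FA matrix (Beta-distributed, rescaled into
    ``[fa_min, fa_max]``), and the sorted tuple of planted hub indices.
    """
    cfg.validate()
    adj, hubs = _topology(cfg, np.random.default_rng([seed, _STREAM_TOPOLOGY]))
    n = cfg.n_regions
    iu, ju = np.nonzero(np.triu(adj, k=1))

    rng_w = np.random.default_rng([seed, _STREAM_WEIGHTS])
    w = rng_w.lognormal(mean=cfg.nos_mu, sigma=cfg.nos_sigma, size=iu.size)
    w = np.maximum(np.rint(w), 1.0)
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True
    # multiplier applies once per hub endpoint: hub-hub edges get it squared,
    # concentrating weight inside the rich club
    mult = cfg.hub_strength_multiplier ** (
        is_hub[iu].astype(int) + is_hub[ju].astype(int)
    )
    w = np.rint(w * mult)

    rng_fa = np.random.default_rng([seed, _STREAM_FA])
    fa_raw = rng_fa.beta(cfg.fa_alpha, cfg.fa_beta, size=iu.size)
    if cfg.fa_nos_correlation > 0:
        # blend FA toward the NoS quantile rank to mimic the empirical
        # positive FA-NoS association
        rank = stats_rank(w)
        fa_raw = (1 - cfg.fa_nos_correlation) * fa_raw + cfg.fa_nos_correlation * rank
    fa_vals = cfg.fa_min + (cfg.fa_max - cfg.fa_min) * fa_raw

    nos = np.zeros((n, n))
    fa = np.zeros((n, n))
    nos[iu, ju] = w
    fa[iu, ju] = fa_vals
    nos += nos.T
    fa += fa.T
    return (
        ConnectivityMatrix(nos, MatrixRole.NOS),
        ConnectivityMatrix(fa, MatrixRole.FA),
        tuple(int(h) for h in hubs),
    )


def stats_rank(x: np.ndarray) -> np.ndarray:
    """Ranks rescaled to (0, 1), ties by order of appearance."""
    order = np.argsort(x, kind="stable")
    rank = np.empty_like(order, dtype=float)
    rank[order] = np.arange(1, x.size + 1)
    return rank / (x.size + 1)


def simulate_cohort(cfg: SimulationConfig, seed: int) -> Cohort:
    """Generate a multi-group cohort around one base connectome.

    Each subject is the base connectome with multiplicative log-normal
    weight noise (sd ``subject_noise_sigma``) and small additive FA
    noise; the group's attenuation factor then scales every hub-incident
    NoS weight, so group differences are concentrated on hub connectivity
    exactly as the comparison pipeline expects.
    """
    cfg.validate()
    base_nos, base_fa, hubs = simulate_connectome(cfg, seed)
    n = cfg.n_regions
    edge = base_nos.values > 0
    is_hub = np.zeros(n, dtype=bool)
    is_hub[list(hubs)] = True
    hub_mask = (is_hub[:, None] | is_hub[None, :]) & edge

    rng = np.random.default_rng([seed, _STREAM_SUBJECTS])
    rows = []
    matrices: dict[str, tuple[ConnectivityMatrix, ConnectivityMatrix]] = {}
    for group, count in cfg.n_subjects.items():
        atten = cfg.group_effects.get(group, 1.0)
        for s in range(count):
            noise = np.triu(
                rng.lognormal(0.0, cfg.subject_noise_sigma, size=(n, n)), k=1
            )
            noise += noise.T
            nos_vals = base_nos.values * noise
            nos_vals[hub_mask] *= atten
            fa_noise = np.triu(rng.normal(0.0, 0.02, size=(n, n)), k=1)
            fa_noise += fa_noise.T
            fa_vals = np.where(
                edge, np.clip(base_fa.values + fa_noise, 0.05, 0.95), 0.0
            )
            subject_id = f"{group}_{s:03d}"
            matrices[subject_id] = (
                ConnectivityMatrix(nos_vals, MatrixRole.NOS),
                ConnectivityMatrix(fa_vals, MatrixRole.FA),
            )
            rows.append({"subject_id": subject_id, "group": group})
    return Cohort(
        manifest=pd.DataFrame(rows),
        matrices=matrices,
        planted_hubs=hubs,
        base_nos=base_nos,
        base_fa=base_fa,
    )
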