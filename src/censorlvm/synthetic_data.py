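"""Synthetic censored datasets with known ground truth.

Two generators:

* a 2D four-Gaussian mixture with right censoring in the first dimension —
  the minimal example on which substitution visibly biases a PCA while the
  censoring-aware model keeps the censored tail open;
* a qPCR-like simulator: cell populations as Gaussian clusters in a
  low-dimensional latent space, mapped linearly to Ct space, with a
  housekeeping block carrying a per-cell offset (cell-size proxy),
  long-tailed Ct distributions, gene-dependent censoring fractions from
  zero to high, and a hard measurement ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import censor_noise as cn
from .data_io import CtMatrix

DEFAULT_TOY_MEANS = ((0.0, 0.0), (3.0, 0.0), (0.0, 3.0), (3.0, 3.0))


@dataclass
class SyntheticDataset:
    """Generated data plus the uncensored truth.

    ``observed`` is a model-orientation :class:`NoiseAssignment` for the toy
    generator, or a :class:`CtMatrix` (raw Ct orientation) for the qPCR
    simulator.  ``true_values`` are the values before censoring, in the same
    orientation as ``observed``.
    """

    true_values: np.ndarray
    observed: object
    component_labels: np.ndarray
    true_latents: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    seed: int = 0


def four_gaussian_toy(
    n_per_component: int = 100,
    means=DEFAULT_TOY_MEANS,
    cov=None,
    censor_bound: float = 2.0,
    censor_dim: int = 0,
    censor_noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Mixture of four 2D Gaussians, right-censored in one dimension.

    Values of dimension ``censor_dim`` above ``censor_bound`` are flagged
    censored; their stored value is the bound (a placeholder).  The default
    layout puts one pair of components straddling the bound.
    ``censor_noise_sd > 0`` makes the censoring decision noisy (censored iff
    ``value + u > bound`` with ``u ~ N(0, sd^2)``): the generative censoring
    mechanism then has probit slope ``1/sd`` instead of a hard step.
    """
    means = np.asarray(means, dtype=float)
    if means.shape[1] != 2:
        raise ValueError("components must be 2D")
    cov = np.eye(2) if cov is None else np.asarray(cov, dtype=float)
    if np.linalg.det(cov) <= 0:
        raise ValueError("degenerate component covariance")
    rng = np.random.default_rng(seed)
    comps = []
    labels = []
    for k, mu in enumerate(means):
        comps.append(rng.multivariate_normal(mu, cov, size=n_per_component))
        labels += [f"comp_{k}"] * n_per_component
    truth = np.vstack(comps)
    labels = np.asarray(labels)
    censored = np.zeros(truth.shape, dtype=bool)
    decision = truth[:, censor_dim]
    if censor_noise_sd > 0:
        decision = decision + rng.normal(scale=censor_noise_sd, size=len(decision))
    censored[:, censor_dim] = decision > censor_bound

    kind = np.where(censored, cn.CENSORED_RIGHT, cn.GAUSSIAN)
    y = np.where(censored, censor_bound, truth)
    noise = cn.NoiseAssignment(
        kind=kind, y=y,
        b1=np.full(truth.shape, censor_bound), b2=np.full(truth.shape, censor_bound + 1.0),
    )
    return SyntheticDataset(
        true_values=truth, observed=noise, component_labels=labels,
        true_latents=truth.copy(), seed=seed,
        params=dict(n_per_component=n_per_component, censor_bound=censor_bound,
                    censor_dim=censor_dim),
    )


def default_censor_profile(n_targets: int, high: float = 0.6) -> np.ndarray:
    """Gene-dependent target censoring fractions spanning 0 to ``high``."""
    return np.linspace(0.0, high, n_targets)


def moderate_censor_profile(n_targets: int) -> np.ndarray:
    """Moderate censoring: none in half the genes, 30-50% in the other half."""
    n_cens = n_targets // 2
    prof = np.zeros(n_targets)
    prof[n_targets - n_cens:] = np.linspace(0.3, 0.5, n_cens)
    return prof


def qpcr_simulator(
    n_cells: int = 300,
    n_genes: int = 12,
    n_populations: int = 4,
    hk_count: int = 2,
    lod: float = 28.0,
    ct_max: float = 40.0,
    censor_profile: np.ndarray | None = None,
    seed: int = 0,
    q_latent: int = 2,
    c0: float = 30.0,
    pop_spread: float = 1.0,
    within_sd: float = 0.7,
    gene_scale: tuple[float, float] = (1.5, 3.0),
    noise_sd: float = 0.5,
    hk_base: float = 16.0,
    cell_offset_sd: float = 1.0,
    off_gap: float = 5.0,
) -> SyntheticDataset:
    """Simulate a single-cell qPCR Ct matrix with known population structure.

    Populations are Gaussian clusters in a ``q_latent``-dimensional latent
    space, mapped linearly to target-gene expression; expression converts to
    Ct via ``Ct = c0 - expression`` (monotone decreasing: more transcript,
    fewer cycles).  Every gene, housekeeping included, receives a shared
    per-cell offset emulating cell-size/efficiency variation, which the
    housekeeping normalization later removes.

    Non-detects in single-cell qPCR mix two regimes: transcript levels
    trailing off toward the detection limit, and genes that are simply off
    in some cell populations (true Ct far beyond the LOD).  Each gene with
    a nonzero target censoring fraction is therefore switched off — shifted
    ``off_gap`` cycles deeper than its detected range — in a random subset
    of populations covering roughly that fraction of cells, producing the
    bimodal per-gene Ct distributions seen in such data.  Per-gene offsets
    are then calibrated so realized censoring fractions track
    ``censor_profile``; values at or above the LOD are censored, and the
    stored Ct is capped at ``ct_max``.
    """
    if hk_count < 1:
        raise ValueError("need at least one housekeeping gene")
    n_targets = n_genes - hk_count
    if n_targets < 1:
        raise ValueError("need at least one non-housekeeping gene")
    profile = (default_censor_profile(n_targets) if censor_profile is None
               else np.asarray(censor_profile, dtype=float))
    if profile.shape != (n_targets,):
        raise ValueError(f"censor_profile must have length {n_targets}")
    if np.any((profile < 0) | (profile >= 1.0)):
        raise ValueError("target censoring fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    centers = rng.normal(scale=pop_spread, size=(n_populations, q_latent))
    pop = rng.integers(n_populations, size=n_cells)
    Z = centers[pop] + rng.normal(scale=within_sd, size=(n_cells, q_latent))
    W = rng.standard_normal((n_targets, q_latent))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    W *= rng.uniform(*gene_scale, size=(n_targets, 1))
    expr = Z @ W.T + rng.normal(scale=noise_sd, size=(n_cells, n_targets))
    delta = rng.normal(scale=cell_offset_sd, size=n_cells)  # cell-size proxy

    # off-mode: censorable genes are silent in a population subset whose
    # cell share approximates the target fraction (lack of transcription)
    pop_frac = np.bincount(pop, minlength=n_populations) / n_cells
    for j in range(n_targets):
        if profile[j] <= 0.0 or off_gap <= 0.0:
            continue
        perm = rng.permutation(n_populations)
        chosen, total = [], 0.0
        for p in perm:
            if total + pop_frac[p] <= profile[j] + pop_frac[p] / 2:
                chosen.append(p)
                total += pop_frac[p]
            if total >= profile[j]:
                break
        if chosen:
            expr[np.isin(pop, chosen), j] -= off_gap

    # per-gene offset so the realized censoring fraction matches the
    # profile: censored iff Ct >= lod iff (expr - delta) + offset <= c0 - lod
    thresh = c0 - lod
    s = expr - delta[:, None]
    offsets = np.empty(n_targets)
    for j in range(n_targets):
        if profile[j] <= 0.0:
            # keep every value safely detected
            offsets[j] = thresh - s[:, j].min() + 1.0
        else:
            offsets[j] = thresh - np.quantile(s[:, j], profile[j])
    expr = expr + offsets
    ct_targets = c0 - expr

    hk = hk_base + rng.normal(scale=0.1, size=(n_cells, hk_count))
    ct = np.concatenate([hk, ct_targets], axis=1) + delta[:, None]

    lod_vec = np.concatenate([np.full(hk_count, lod), np.full(n_targets, lod)])
    censored = ct >= lod_vec[None, :]
    true_ct = ct.copy()
    ct_stored = np.minimum(ct, ct_max)
    gene_ids = [f"hk_{i}" for i in range(hk_count)] + [f"gene_{j}" for j in range(n_targets)]
    labels = np.array([f"pop_{p}" for p in pop])
    ctm = CtMatrix(
        values=ct_stored, censored=censored,
        missing=np.zeros_like(censored),
        lod=lod_vec, gene_ids=gene_ids,
        cell_ids=[f"cell_{i}" for i in range(n_cells)],
        housekeeping=gene_ids[:hk_count], cell_labels=labels,
    )
    return SyntheticDataset(
        true_values=true_ct, observed=ctm, component_labels=labels,
        true_latents=Z, seed=seed,
        params=dict(n_cells=n_cells, n_genes=n_genes, n_populations=n_populations,
                    hk_count=hk_count, lod=lod, ct_max=ct_max,
                    profile=profile.tolist(), c0=c0),
    )
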