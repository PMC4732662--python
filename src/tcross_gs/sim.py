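"""Synthetic breeding-study generator: structured inbred genotypes and
multi-location testcross phenotypes with known truth.

The generator emulates a hybrid-canola testcross design: a few hundred fully
homozygous pollinator lines drawn from divergent subpopulations, genotyped at
thousands of biallelic SNPs, crossed to a small set of male-sterile testers
and evaluated in unreplicated trials at several locations.

Population structure follows a Balding–Nichols model: each marker has an
ancestral allele frequency drawn uniformly in [0.1, 0.9]; subpopulation s
draws its frequency from Beta(p(1-F_s)/F_s, (1-p)(1-F_s)/F_s), so F_s = 0
reproduces the ancestral frequency exactly and larger F_s increases
between-subpopulation divergence. Lines are fully inbred, so raw calls are
-1/+1 only; heterozygote-like fractional codes arise downstream solely from
mean imputation.

Phenotypes follow y = mu + GCA_p + tester_t + SCA_{p,t} + location_l + eps
with GCA_p = sum_q x_{p,q} a_q over additive QTL effects, fixed tester and
location offsets, an SCA term scaled to a chosen fraction of the GCA
variance, and a residual variance solved from the realized hybrid genetic
variance so the broad-sense heritability sigma2_g / (sigma2_g + sigma2_e/n)
hits the requested target exactly on the simulated sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .qc import MarkerPanel

_STAGE_CODES = {
    "ancestral": 0,
    "subpop_freqs": 1,
    "genotypes": 2,
    "missing": 3,
    "qtl": 4,
    "sca": 5,
    "residual": 6,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named, reproducible RNG stream for one simulation stage."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_CODES[stage],))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    """Parameters of one simulated testcross study.

    Defaults reproduce the shape of the motivating study: 475 inbred
    pollinators in three subpopulations of 286/147/42, ~24k biallelic
    markers, two testers, four locations. ``fst`` may be a scalar or one
    value per subpopulation. ``qtl_phase_flip`` (one sign per subpopulation)
    reverses the marker-QTL linkage phase inside flagged subpopulations, a
    device for studying cross-subpopulation training.
    """

    n_lines: int = 475
    subpop_sizes: Sequence[int] = (286, 147, 42)
    n_markers: int = 24403
    fst: float | Sequence[float] = 0.1
    n_qtl: int = 100
    qtl_effect_sd: float = 1.0
    h2_target: float = 0.7
    n_testers: int = 2
    n_locations: int = 4
    sca_variance_fraction: float = 0.1
    missing_rate: float = 0.02
    seed: int = 0
    trait: str = "trait"
    mu: float = 0.0
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    qtl_phase_flip: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if sum(self.subpop_sizes) != self.n_lines:
            raise ValueError(
                f"subpop_sizes sum to {sum(self.subpop_sizes)}, expected n_lines={self.n_lines}"
            )
        for f in self.fst_per_subpop():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"fst must lie in [0, 1), got {f}")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if not 0.0 < self.h2_target <= 1.0:
            raise ValueError("h2_target must lie in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.qtl_phase_flip is not None and len(self.qtl_phase_flip) != len(
            self.subpop_sizes
        ):
            raise ValueError("qtl_phase_flip needs one sign per subpopulation")

    def fst_per_subpop(self) -> list[float]:
        if np.isscalar(self.fst):
            return [float(self.fst)] * len(self.subpop_sizes)
        return [float(f) for f in self.fst]


@dataclass
class TruthRecord:
    """Ground truth of a simulated study, for parameter-recovery checks."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_gca: pd.Series
    subpop_labels: pd.Series
    true_h2: float | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.qtl_indices) != len(self.qtl_effects):
            raise ValueError("qtl_indices and qtl_effects lengths differ")

    def to_dict(self) -> dict:
        return {
            "qtl_indices": [int(i) for i in self.qtl_indices],
            "qtl_effects": [float(a) for a in self.qtl_effects],
            "true_gca": {k: float(v) for k, v in self.true_gca.items()},
            "subpop_labels": {k: str(v) for k, v in self.subpop_labels.items()},
            "true_h2": None if self.true_h2 is None else float(self.true_h2),
            "seed": int(self.seed),
        }


def simulate_structured_genotypes(config: SimConfig) -> tuple[MarkerPanel, TruthRecord]:
    """Draw a structured inbred genotype panel plus its truth record.

    Returns the raw (pre-QC) panel: calls are ±1 with NaN injected at
    ``missing_rate``. True GCA values are computed from the complete calls,
    before missingness.
    """
    rng_anc = stage_rng(config.seed, "ancestral")
    lo, hi = config.ancestral_freq_range
    p_anc = rng_anc.uniform(lo, hi, size=config.n_markers)

    rng_sub = stage_rng(config.seed, "subpop_freqs")
    fsts = config.fst_per_subpop()
    sub_freqs = np.empty((len(fsts), config.n_markers))
    for s, f in enumerate(fsts):
        if f == 0.0:
            sub_freqs[s] = p_anc
        else:
            scale = (1.0 - f) / f
            sub_freqs[s] = rng_sub.beta(p_anc * scale, (1.0 - p_anc) * scale)

    rng_g = stage_rng(config.seed, "genotypes")
    blocks = []
    labels = []
    for s, size in enumerate(config.subpop_sizes):
        u = rng_g.random((size, config.n_markers))
        blocks.append(np.where(u < sub_freqs[s], 1.0, -1.0))
        labels.extend([f"C{s + 1}"] * size)
    complete = np.vstack(blocks)

    line_ids = [f"L{i + 1:04d}" for i in range(config.n_lines)]
    marker_ids = [f"M{j + 1:06d}" for j in range(config.n_markers)]
    subpop = pd.Series(labels, index=line_ids, name="subpop")

    rng_q = stage_rng(config.seed, "qtl")
    qtl_idx = np.sort(rng_q.choice(config.n_markers, size=config.n_qtl, replace=False))
    effects = rng_q.normal(0.0, config.qtl_effect_sd, size=config.n_qtl)
    gca = complete[:, qtl_idx] @ effects
    if config.qtl_phase_flip is not None:
        signs = np.repeat(
            np.asarray(config.qtl_phase_flip, dtype=float), config.subpop_sizes
        )
        gca = gca * signs

    calls = complete.copy()
    if config.missing_rate > 0.0:
        rng_m = stage_rng(config.seed, "missing")
        mask = rng_m.random(calls.shape) < config.missing_rate
        calls[mask] = np.nan

    panel = MarkerPanel(
        calls=pd.DataFrame(calls, index=line_ids, columns=marker_ids)
    )
    truth = TruthRecord(
        qtl_indices=qtl_idx,
        qtl_effects=effects,
        true_gca=pd.Series(gca, index=line_ids, name="true_gca"),
        subpop_labels=subpop,
        seed=config.seed,
    )
    return panel, truth


def simulate_testcross_phenotypes(
    genotypes: MarkerPanel,
    truth: TruthRecord,
    config: SimConfig,
) -> pd.DataFrame:
    """Simulate the multi-location testcross trial for one trait.

    Produces one record per (pollinator, tester, location) in long format
    with columns pollinator, tester, location, trait, value. Tester and
    location effects are fixed constants spread around zero; the residual
    variance is solved so the realized broad-sense heritability (with
    n = ``n_locations``) equals ``h2_target``, which is then stored in
    ``truth.true_h2``.
    """
    if not truth.true_gca.index.equals(pd.Index(genotypes.line_ids)):
        raise ValueError("truth does not match the genotype panel's lines")

    gca = truth.true_gca.to_numpy()
    n_p, n_t, n_l = len(gca), config.n_testers, config.n_locations
    scale = gca.std() if gca.std() > 0 else 1.0

    # fixed tester/location offsets, symmetric about zero
    tester_eff = np.linspace(-0.5, 0.5, n_t) * scale if n_t > 1 else np.zeros(1)
    loc_eff = np.linspace(-1.0, 1.0, n_l) * scale if n_l > 1 else np.zeros(1)

    var_gca = gca.var()
    rng_sca = stage_rng(config.seed, "sca")
    sca_sd = np.sqrt(config.sca_variance_fraction * var_gca)
    sca = rng_sca.normal(0.0, sca_sd, size=(n_p, n_t)) if sca_sd > 0 else np.zeros((n_p, n_t))

    # hybrid genetic values and realized genetic variance among hybrids
    genetic = gca[:, None] + tester_eff[None, :] + sca
    sigma2_g = genetic.var()
    if sigma2_g == 0.0 and config.h2_target < 1.0:
        raise ValueError("zero genetic variance: cannot calibrate residual noise")
    sigma2_e = n_l * sigma2_g * (1.0 - config.h2_target) / config.h2_target

    rng_e = stage_rng(config.seed, "residual")
    eps = (
        rng_e.normal(0.0, np.sqrt(sigma2_e), size=(n_p, n_t, n_l))
        if sigma2_e > 0
        else np.zeros((n_p, n_t, n_l))
    )
    y = config.mu + genetic[:, :, None] + loc_eff[None, None, :] + eps

    truth.true_h2 = float(sigma2_g / (sigma2_g + sigma2_e / n_l))
    truth.extras.update(
        {
            "sigma2_g": float(sigma2_g),
            "sigma2_e": float(sigma2_e),
            "tester_effects": tester_eff.tolist(),
            "location_effects": loc_eff.tolist(),
        }
    )

    pollinators = list(truth.true_gca.index)
    testers = [f"T{t + 1}" for t in range(n_t)]
    locations = [f"Loc{l + 1}" for l in range(n_l)]
    idx = pd.MultiIndex.from_product(
        [pollinators, testers, locations], names=["pollinator", "tester", "location"]
    )
    out = pd.DataFrame(index=idx).reset_index()
    out["trait"] = config.trait
    out["value"] = y.ravel()
    return out


def simulate_study(config: SimConfig) -> tuple[MarkerPanel, pd.DataFrame, TruthRecord]:
    """Genotypes plus phenotypes in one call."""
    panel, truth = simulate_structured_genotypes(config)
    trials = simulate_testcross_phenotypes(panel, truth, config)
    return panel, trials, truth
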