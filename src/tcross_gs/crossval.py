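"""Cross-validation engine for genomic prediction accuracy.

Each round draws a training population (TP) of round(tp_fraction * N) lines
without replacement from the scenario's sampling frame, fits RR-BLUP on the
TP, predicts the validation population (VP) and records the prediction
accuracy r_GPA — the Pearson correlation between predicted and observed
values. Summaries report the mean over rounds and the standard error of that
mean (sd of the per-round accuracies / sqrt(rounds)). Rounds whose VP is
degenerate (zero variance in either vector) are excluded from the summary
and counted.

Scenarios
---------
whole_population      TP and VP drawn from all lines.
within_cluster        TP and VP drawn only from one cluster.
cross_cluster_train   TP sampled from *all* lines but sized to match the
                      corresponding within-cluster TP; VP restricted to
                      held-out members of the target cluster.
structure_covariate   whole-population split with cluster-membership
                      indicators added as fixed covariates to fit and predict.

Reproducibility: round r of a run with master seed s uses the RNG stream
SeedSequence([s, r]); a TP-fraction sweep gives fraction i the derived master
seed SeedSequence([s, 1_000_000 + i]) so every point, and every single round,
can be re-run in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rrblup import RRBLUP

logger = logging.getLogger(__name__)

SCENARIOS = (
    "whole_population",
    "within_cluster",
    "cross_cluster_train",
    "structure_covariate",
)
MIN_CLUSTER_SIZE = 15  # within-cluster validation refused below this: TP/VP both become tiny


@dataclass
class ScenarioSpec:
    name: str = "whole_population"
    cluster: str | None = None
    tp_fraction: float = 0.7
    n_rounds: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIOS}")
        if not 0.0 < self.tp_fraction < 1.0:
            raise ValueError("tp_fraction must lie strictly between 0 and 1")
        if self.name in ("within_cluster", "cross_cluster_train") and self.cluster is None:
            raise ValueError(f"scenario {self.name!r} needs a target cluster")


@dataclass
class CVResult:
    trait: str
    scenario: str
    accuracies: np.ndarray  # one entry per round; NaN marks degenerate rounds
    mean_r_gpa: float
    se: float
    n_rounds: int
    seed: int
    tp_fraction: float
    n_degenerate: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "scenario": self.scenario,
            "mean_r_gpa": self.mean_r_gpa,
            "se": self.se,
            "n_rounds": self.n_rounds,
            "seed": self.seed,
            "tp_fraction": self.tp_fraction,
            "n_degenerate": self.n_degenerate,
            **self.extras,
        }


def accuracy(predicted, observed) -> float:
    """r_GPA: sample Pearson correlation between predicted and observed.

    Returns NaN when either vector has zero variance (callers count and
    exclude such rounds).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed lengths differ")
    if len(p) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(p) == 0.0 or np.ptp(o) == 0.0:
        return np.nan
    return float(np.corrcoef(p, o)[0, 1])


def _round_rng(seed: int, round_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(round_idx)]))


def _derive_seed(seed: int, slot: int) -> int:
    state = np.random.SeedSequence([int(seed), 1_000_000 + int(slot)]).generate_state(1)
    return int(state[0] % (2**31))


def _summarize(acc: np.ndarray) -> tuple[float, float, int]:
    valid = acc[~np.isnan(acc)]
    n_deg = int(np.isnan(acc).sum())
    if valid.size == 0:
        return np.nan, np.nan, n_deg
    mean = float(valid.mean())
    se = float(valid.std(ddof=1) / np.sqrt(valid.size)) if valid.size > 1 else 0.0
    return mean, se, n_deg


def _cv_engine(
    y: np.ndarray,
    X: np.ndarray,
    frame: np.ndarray,
    tp_size: int,
    n_rounds: int,
    seed: int,
    vp_frame: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Core loop over rounds; ``frame``/``vp_frame`` hold row indices into X."""
    acc = np.empty(n_rounds)
    for r in range(n_rounds):
        rng = _round_rng(seed, r)
        tp = rng.choice(frame, size=tp_size, replace=False)
        pool = frame if vp_frame is None else vp_frame
        vp = np.setdiff1d(pool, tp, assume_unique=False)
        if vp.size < 3:
            raise ValueError(f"validation population of {vp.size} lines (<3) in round {r}")
        model = RRBLUP()
        if covariates is None:
            model.fit(X[tp], y[tp])
            pred = model.predict(X[vp])
        else:
            model.fit(X[tp], y[tp], W=covariates[tp])
            pred = model.predict(X[vp], W=covariates[vp])
        acc[r] = accuracy(pred, y[vp])
    return acc


def _align(gca: pd.DataFrame, genotypes, trait: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Shared lines between the GCA table and the genotype matrix."""
    coded = genotypes.coded if hasattr(genotypes, "coded") else genotypes
    sub = gca[gca["trait"] == trait] if "trait" in gca.columns else gca
    yser = sub.set_index("pollinator")["gca"]
    shared = [l for l in coded.index if l in yser.index]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} lines shared between GCA and genotypes (<10)")
    return (
        yser.loc[shared].to_numpy(dtype=float),
        coded.loc[shared].to_numpy(dtype=float),
        shared,
    )


def run_cv(
    gca: pd.DataFrame,
    genotypes,
    spec: ScenarioSpec,
    trait: str | None = None,
) -> CVResult:
    """Whole-frame cross-validation (the whole_population scenario)."""
    trait = trait or (gca["trait"].iloc[0] if "trait" in gca.columns else "trait")
    y, X, shared = _align(gca, genotypes, trait)
    n = len(shared)
    tp_size = int(round(spec.tp_fraction * n))
    if n - tp_size < 3:
        raise ValueError("validation population smaller than 3 lines")
    acc = _cv_engine(y, X, np.arange(n), tp_size, spec.n_rounds, spec.seed)
    mean, se, n_deg = _summarize(acc)
    if n_deg:
        logger.warning("run_cv: %d degenerate rounds excluded", n_deg)
    return CVResult(
        trait=trait,
        scenario=spec.name,
        accuracies=acc,
        mean_r_gpa=mean,
        se=se,
        n_rounds=spec.n_rounds,
        seed=spec.seed,
        tp_fraction=spec.tp_fraction,
        n_degenerate=n_deg,
        extras={"n_lines": n, "tp_size": tp_size},
    )


def run_scenario(
    spec: ScenarioSpec,
    gca: pd.DataFrame,
    genotypes,
    clusters: pd.Series | None = None,
    trait: str | None = None,
) -> CVResult:
    """Dispatch one prediction scenario; ``clusters`` maps line id -> label."""
    trait = trait or (gca["trait"].iloc[0] if "trait" in gca.columns else "trait")
    if spec.name == "whole_population":
        return run_cv(gca, genotypes, spec, trait=trait)

    if clusters is None:
        raise ValueError(f"scenario {spec.name!r} needs cluster labels")
    y, X, shared = _align(gca, genotypes, trait)
    labels = clusters.reindex(shared)
    if labels.isna().any():
        raise ValueError("cluster labels do not cover all shared lines")
    n = len(shared)

    if spec.name == "structure_covariate":
        W = pd.get_dummies(labels, drop_first=True, dtype=float).to_numpy()
        tp_size = int(round(spec.tp_fraction * n))
        acc = _cv_engine(
            y, X, np.arange(n), tp_size, spec.n_rounds, spec.seed, covariates=W
        )
    else:
        members = np.flatnonzero((labels == spec.cluster).to_numpy())
        if members.size == 0:
            raise ValueError(f"cluster {spec.cluster!r} not found")
        if members.size < MIN_CLUSTER_SIZE:
            raise ValueError(
                f"cluster {spec.cluster!r} has {members.size} lines "
                f"(<{MIN_CLUSTER_SIZE}): too small for within-cluster validation"
            )
        tp_size = int(round(spec.tp_fraction * members.size))
        if spec.name == "within_cluster":
            acc = _cv_engine(y, X, members, tp_size, spec.n_rounds, spec.seed)
        else:  # cross_cluster_train: TP from everywhere, size-matched; VP inside the cluster
            acc = _cv_engine(
                y,
                X,
                np.arange(n),
                tp_size,
                spec.n_rounds,
                spec.seed,
                vp_frame=members,
            )
    mean, se, n_deg = _summarize(acc)
    return CVResult(
        trait=trait,
        scenario=spec.name,
        accuracies=acc,
        mean_r_gpa=mean,
        se=se,
        n_rounds=spec.n_rounds,
        seed=spec.seed,
        tp_fraction=spec.tp_fraction,
        n_degenerate=n_deg,
        extras={"cluster": spec.cluster, "n_lines": n, "tp_size": tp_size},
    )


def tp_sweep(
    gca: pd.DataFrame,
    genotypes,
    fractions=tuple(np.round(np.arange(0.1, 0.91, 0.1), 2)),
    n_rounds: int = 100,
    seed: int = 0,
    trait: str | None = None,
) -> list[CVResult]:
    """Accuracy-versus-training-fraction curve.

    Each fraction runs an independent whole-population CV with its own
    derived master seed. Fractions leaving fewer than 3 validation lines are
    skipped with a warning.
    """
    results = []
    for i, f in enumerate(fractions):
        if not 0.0 < f < 1.0:
            raise ValueError(f"fraction {f} outside (0, 1)")
        spec = ScenarioSpec(
            name="whole_population",
            tp_fraction=float(f),
            n_rounds=n_rounds,
            seed=_derive_seed(seed, i),
        )
        try:
            results.append(run_cv(gca, genotypes, spec, trait=trait))
        except ValueError as exc:
            warnings.warn(f"skipping fraction {f}: {exc}")
    return results


def sweep_frame(results: list[CVResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tp_fraction": [r.tp_fraction for r in results],
            "mean_r_gpa": [r.mean_r_gpa for r in results],
            "se": [r.se for r in results],
        }
    )
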