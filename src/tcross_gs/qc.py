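"""SNP panel quality control: missingness filter, monomorphic removal, MAF
filter and mean imputation.

Markers are coded additively: homozygote for one allele = -1, heterozygote = 0,
homozygote for the other allele = +1, missing = NaN.  Lines are never removed;
only markers are filtered.  Filters are applied in a fixed order —
(1) missingness, (2) monomorphic, (3) minor-allele frequency — and each removed
marker is attributed to the first rule that triggers.  Both thresholds are
strict inequalities: a marker with exactly 20% missing calls or MAF exactly
0.05 is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

VALID_CALLS = (-1.0, 0.0, 1.0)


class QCError(ValueError):
    """Raised when quality control cannot proceed (e.g. the panel empties)."""


@dataclass
class MarkerPanel:
    """Raw lines x markers call matrix with missing values as NaN.

    ``calls`` is a DataFrame indexed by line id with one column per marker id;
    values are in {-1, 0, +1, NaN}.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.calls.index.is_unique:
            raise ValueError("line ids must be unique")
        if not self.calls.columns.is_unique:
            raise ValueError("marker ids must be unique")
        self.calls = self.calls.astype(float)

    @property
    def line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]


@dataclass
class GenotypeMatrix:
    """Imputed, filtered additive genotype matrix — the X of the RR-BLUP model.

    ``coded`` holds real values (mean imputation produces fractional calls);
    ``allele_freqs`` the per-marker minor-allele frequency computed on the
    pre-imputation non-missing calls.
    """

    coded: pd.DataFrame
    allele_freqs: pd.Series

    def __post_init__(self) -> None:
        if self.coded.isna().any().any():
            raise ValueError("GenotypeMatrix must not contain missing values")

    @property
    def line_ids(self) -> list[str]:
        return list(self.coded.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.coded.columns)

    @property
    def values(self) -> np.ndarray:
        return self.coded.to_numpy(dtype=float)


@dataclass
class QCReport:
    n_input_markers: int
    n_removed_missingness: int
    n_removed_monomorphic: int
    n_removed_maf: int
    n_retained: int
    maf_min: float = 0.05
    max_missing: float = 0.20
    removed_markers: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_missingness
            + self.n_removed_monomorphic
            + self.n_removed_maf
        )
        if self.n_input_markers - removed != self.n_retained:
            raise ValueError("QCReport counts are inconsistent")

    def to_dict(self) -> dict:
        return asdict(self)


def _minor_allele_frequency(col: np.ndarray) -> float:
    """MAF of one marker from non-missing additive calls.

    Each fully scored call contributes two alleles; the frequency of the +1
    allele is (mean+1)/2 and the minor-allele convention folds it to <= 0.5.
    """
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise QCError("marker has no non-missing calls; frequency undefined")
    f = (obs.mean() + 1.0) / 2.0
    return float(min(f, 1.0 - f))


def allele_frequency(panel: MarkerPanel, marker: str) -> float:
    """Minor-allele frequency of ``marker`` over non-missing calls, in [0, 0.5]."""
    if marker not in panel.calls.columns:
        raise KeyError(f"unknown marker {marker!r}")
    return _minor_allele_frequency(panel.calls[marker].to_numpy(dtype=float))


class MarkerQC(TransformerMixin, BaseEstimator):
    """Marker filtering and mean imputation as a scikit-learn transformer.

    Parameters
    ----------
    maf_min : float
        Markers with minor-allele frequency strictly below this are removed.
    max_missing : float
        Markers with a fraction of missing calls strictly above this are
        removed.

    Attributes
    ----------
    keep_markers_ : list of retained marker ids
    impute_means_ : pd.Series, per retained marker mean of non-missing calls
    allele_freqs_ : pd.Series, per retained marker MAF
    report_ : QCReport
    """

    def __init__(self, maf_min: float = 0.05, max_missing: float = 0.20):
        self.maf_min = maf_min
        self.max_missing = max_missing

    def fit(self, X, y=None):
        calls = X.calls if isinstance(X, MarkerPanel) else pd.DataFrame(X)
        if calls.shape[1] == 0:
            raise QCError("empty panel: no markers to filter")
        vals = calls.to_numpy(dtype=float)
        n_lines, n_markers = vals.shape
        miss_frac = np.isnan(vals).mean(axis=0)

        removed: dict[str, str] = {}
        stage1 = miss_frac > self.max_missing  # strict: >20% removed
        for m in calls.columns[stage1]:
            removed[m] = "missingness"

        alive = ~stage1
        # monomorphic: a single distinct non-missing call value
        for j in np.flatnonzero(alive):
            obs = vals[:, j][~np.isnan(vals[:, j])]
            if np.unique(obs).size <= 1:
                removed[calls.columns[j]] = "monomorphic"
                alive[j] = False

        freqs = {}
        for j in np.flatnonzero(alive):
            maf = _minor_allele_frequency(vals[:, j])
            if maf < self.maf_min:  # strict: exactly maf_min retained
                removed[calls.columns[j]] = "maf"
                alive[j] = False
            else:
                freqs[calls.columns[j]] = maf

        keep = [m for m in calls.columns if m not in removed]
        if not keep:
            last = "maf" if any(v == "maf" for v in removed.values()) else (
                "monomorphic" if any(v == "monomorphic" for v in removed.values())
                else "missingness"
            )
            raise QCError(f"no markers survive quality control (stage: {last})")

        kept = calls[keep]
        self.keep_markers_ = keep
        self.impute_means_ = kept.mean(axis=0, skipna=True)
        self.allele_freqs_ = pd.Series(freqs).reindex(keep)
        counts = pd.Series(list(removed.values()))
        self.report_ = QCReport(
            n_input_markers=n_markers,
            n_removed_missingness=int((counts == "missingness").sum()),
            n_removed_monomorphic=int((counts == "monomorphic").sum()),
            n_removed_maf=int((counts == "maf").sum()),
            n_retained=len(keep),
            maf_min=self.maf_min,
            max_missing=self.max_missing,
            removed_markers=removed,
        )
        self.n_features_in_ = n_markers
        return self

    def transform(self, X) -> pd.DataFrame:
        calls = X.calls if isinstance(X, MarkerPanel) else pd.DataFrame(X)
        missing_cols = [m for m in self.keep_markers_ if m not in calls.columns]
        if missing_cols:
            raise KeyError(f"panel lacks retained markers: {missing_cols[:5]}...")
        out = calls[self.keep_markers_].astype(float)
        return out.fillna(self.impute_means_)


def qc_pipeline(
    panel: MarkerPanel,
    maf_min: float = 0.05,
    max_missing: float = 0.20,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter and impute a marker panel; returns the coded matrix and a report.

    Filter order: missingness (> ``max_missing`` removed), monomorphic, then
    MAF (< ``maf_min`` removed, computed on non-missing calls). Remaining
    missing calls are replaced by the marker's mean coded value, which leaves
    every marker's mean (and hence MAF) unchanged.
    """
    qc = MarkerQC(maf_min=maf_min, max_missing=max_missing).fit(panel)
    coded = qc.transform(panel)
    logger.info(
        "QC: %d markers in, %d retained (%d missingness, %d monomorphic, %d MAF)",
        qc.report_.n_input_markers,
        qc.report_.n_retained,
        qc.report_.n_removed_missingness,
        qc.report_.n_removed_monomorphic,
        qc.report_.n_removed_maf,
    )
    return GenotypeMatrix(coded=coded, allele_freqs=qc.allele_freqs_), qc.report_


def import_vcf(path: str) -> MarkerPanel:
    """Read biallelic SNPs from a VCF into a MarkerPanel.

    Genotypes map hom-ref -> -1, het -> 0, hom-alt -> +1, missing -> NaN.
    Records with more than one ALT allele are skipped (counted in the log).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 raises OSError subclasses
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    n_skipped = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code = {0: -1.0, 1: 0.0, 2: np.nan, 3: 1.0}
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        cols[mid] = np.array([code[g] for g in var.gt_types], dtype=float)
    if n_skipped:
        logger.warning("import_vcf: skipped %d multi-allelic records", n_skipped)
    calls = pd.DataFrame(cols, index=samples, dtype=float)
    if not cols:
        calls = pd.DataFrame(index=samples, dtype=float)
    panel = MarkerPanel(calls=calls)
    panel.n_skipped_multiallelic = n_skipped
    return panel
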