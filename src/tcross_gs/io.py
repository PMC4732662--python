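"""Plain-text readers and writers for the pipeline's tabular artifacts.

Genotype tables are TSV/CSV with a header row of marker ids and a first
column of line ids; NA or blank cells mark missing calls. Phenotypes travel
as long-format CSV (pollinator,tester,location,trait,value). A precomputed
wide BLUE table (one row per hybrid, one column per trait) is also accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pheno import validate_trials
from .qc import GenotypeMatrix, MarkerPanel

NA_VALUES = ["", "NA", "NaN", "nan", "."]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_genotype_table(path) -> MarkerPanel:
    df = pd.read_csv(path, sep=_sep(path), index_col=0, na_values=NA_VALUES)
    return MarkerPanel(calls=df.astype(float))


def write_genotype_table(geno, path) -> None:
    df = geno.coded if isinstance(geno, GenotypeMatrix) else geno.calls
    df.to_csv(path, sep=_sep(path), na_rep="NA", index_label="line_id")


def read_coded_matrix(path) -> GenotypeMatrix:
    """Read an already-filtered, imputed genotype matrix."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0, na_values=NA_VALUES)
    if df.isna().any().any():
        raise ValueError("coded matrix contains missing values; run QC first")
    freqs = ((df.mean() + 1.0) / 2.0).clip(0, 1)
    freqs = pd.Series(np.minimum(freqs, 1.0 - freqs), index=df.columns)
    return GenotypeMatrix(coded=df.astype(float), allele_freqs=freqs)


def read_trials(path) -> pd.DataFrame:
    return validate_trials(pd.read_csv(path))


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_blues(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"pollinator", "tester", "trait", "blue"}
    if not need.issubset(df.columns):
        raise ValueError(f"BLUE table needs columns {sorted(need)}")
    return df


def read_blues_wide(path, pollinator_col="pollinator", tester_col="tester") -> pd.DataFrame:
    """Read a wide hybrid x trait BLUE table (one column per trait) to long form."""
    df = pd.read_csv(path, sep=_sep(path))
    traits = [c for c in df.columns if c not in (pollinator_col, tester_col)]
    long = df.melt(
        id_vars=[pollinator_col, tester_col],
        value_vars=traits,
        var_name="trait",
        value_name="blue",
    ).rename(columns={pollinator_col: "pollinator", tester_col: "tester"})
    return long.dropna(subset=["blue"]).reset_index(drop=True)


def write_blues(blues: pd.DataFrame, path) -> None:
    blues.to_csv(path, index=False)


def read_gca(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"pollinator", "trait", "gca"}
    if not need.issubset(df.columns):
        raise ValueError(f"GCA table needs columns {sorted(need)}")
    return df


def write_gca(gca: pd.DataFrame, path) -> None:
    gca.to_csv(path, index=False)


def write_distance_matrix(dist, path) -> None:
    dist.to_frame().to_csv(path, sep="\t", index_label="line_id")


def write_pcoa(result, prefix: Path) -> None:
    n_axes = result.coordinates.shape[1]
    coords = pd.DataFrame(
        result.coordinates,
        index=result.line_ids,
        columns=[f"PCo{i + 1}" for i in range(n_axes)],
    )
    coords.to_csv(Path(prefix) / "pcoa_coordinates.csv", index_label="line_id")
    pd.DataFrame(
        {
            "axis": [f"PCo{i + 1}" for i in range(n_axes)],
            "eigenvalue": result.eigenvalues[:n_axes],
            "explained_variance_pct": result.explained_variance_pct,
        }
    ).to_csv(Path(prefix) / "pcoa_eigenvalues.csv", index=False)


def write_clusters(labels: pd.Series, path) -> None:
    labels.rename("cluster").to_csv(path, index_label="line_id")


def read_clusters(path) -> pd.Series:
    df = pd.read_csv(path, index_col=0)
    return df["cluster"].astype(str)


def write_cv_result(result, rounds_path, summary_path) -> None:
    pd.DataFrame(
        {"round": np.arange(result.n_rounds), "r_gpa": result.accuracies}
    ).to_csv(rounds_path, index=False)
    with open(summary_path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
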