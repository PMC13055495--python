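"""Readers and writers for survey tables, coefficient tables and reports.

All tabular formats are plain text: CSV/TSV for observations and
coefficients, TSV or MatrixMarket for count matrices, TSV/JSON for
classification reports.  Floats in reports are written with 6 significant
digits; comparisons downstream should use tolerances, never string equality.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from multistress.types import (
    InputError,
    InteractionClass,
    SITES,
    StressorCoefficients,
    WARMING,
)

__all__ = [
    "read_survey_table",
    "write_survey_table",
    "read_coefficient_table",
    "write_coefficient_table",
    "coefficients_from_frame",
    "coefficients_to_frame",
    "read_counts",
    "write_counts",
    "write_classification_report",
    "read_classification_report",
    "example_coefficients",
]

_SURVEY_COLS = ["plate_id", "site", "warming", "day", "response", "value"]
_COEF_COLS = [
    "response", "date_label", "link", "alpha",
    "beta_w", "beta_p", "beta_int",
    "se_w", "se_p", "se_int",
    "p_w", "p_p", "p_int", "n_obs",
]
_REPORT_COLS = [
    "response", "date_label", "category", "code", "mild",
    "delta_add", "delta_obs", "beta_int",
    "ratio", "ci_low", "ci_high", "ci_level", "scale",
]


def _sep_for(path: Union[str, Path]) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_survey_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a long-format survey table (CSV or TSV).

    Headers are matched case-insensitively; site and warming levels are
    normalized to lowercase canonical values.  Unknown levels, duplicate
    (plate, day, response) keys and negative values raise a descriptive
    :class:`InputError` naming the offending row (1-based data row number).
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _SURVEY_COLS if c not in df.columns]
    if missing:
        raise InputError(f"survey table {path} missing columns {missing}")
    df = df[_SURVEY_COLS].copy()
    for col, levels in (("site", SITES), ("warming", WARMING)):
        df[col] = df[col].astype(str).str.strip().str.lower()
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise InputError(
                f"unknown {col} level {df.loc[bad, col].iloc[0]!r} at data row {row}; "
                f"expected one of {levels}"
            )
    df["day"] = df["day"].astype(int)
    df["value"] = df["value"].astype(float)
    neg = df["value"] < 0
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0]) + 1
        raise InputError(f"negative value at data row {row}")
    dup = df.duplicated(subset=["plate_id", "day", "response"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        key = df.loc[dup, ["plate_id", "day", "response"]].iloc[0].tolist()
        raise InputError(f"duplicate (plate_id, day, response) key {key} at data row {row}")
    consistency = df.groupby("plate_id")[["site", "warming"]].nunique()
    if (consistency > 1).any().any():
        bad_plate = consistency[(consistency > 1).any(axis=1)].index[0]
        raise InputError(f"plate {bad_plate!r} changes site/warming across rows")
    return df


def write_survey_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[_SURVEY_COLS].to_csv(path, sep=_sep_for(path), index=False)


def coefficients_from_frame(df: pd.DataFrame) -> List[StressorCoefficients]:
    """Turn a coefficient table into typed records (alpha may be NaN)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(StressorCoefficients(
            response=str(row.response), date_label=str(row.date_label),
            link=str(row.link),
            alpha=float(getattr(row, "alpha", math.nan)),
            beta_w=float(row.beta_w), beta_p=float(row.beta_p),
            beta_int=float(row.beta_int),
            se_w=float(row.se_w), se_p=float(row.se_p), se_int=float(row.se_int),
            p_w=float(row.p_w), p_p=float(row.p_p), p_int=float(row.p_int),
            n_obs=int(getattr(row, "n_obs", 0)),
        ))
    return out


def coefficients_to_frame(coefs: Iterable[StressorCoefficients]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(k, c) for c in _COEF_COLS} for k in coefs])


def read_coefficient_table(path: Union[str, Path]) -> List[StressorCoefficients]:
    """Read a TSV coefficient table (one row per fitted 2x2 model)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _COEF_COLS if c not in df.columns and c not in ("alpha", "n_obs")]
    if missing:
        raise InputError(f"coefficient table {path} missing columns {missing}")
    return coefficients_from_frame(df)


def write_coefficient_table(
    coefs: Iterable[StressorCoefficients], path: Union[str, Path]
) -> None:
    coefficients_to_frame(coefs).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_counts(
    counts_path: Union[str, Path],
    samples_path: Union[str, Path],
    genes_path: Optional[Union[str, Path]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes x samples count matrix (TSV or MatrixMarket) + metadata.

    MatrixMarket input needs ``genes_path`` (one gene id per line); sample
    ids are taken from the metadata table's order in that case.
    """
    samples = pd.read_csv(samples_path, sep=_sep_for(samples_path))
    samples.columns = [c.strip().lower() for c in samples.columns]
    for col in ("sample_id", "site", "warming"):
        if col not in samples.columns:
            raise InputError(f"samples table missing column {col!r}")
    if str(counts_path).endswith(".mtx"):
        from scipy.io import mmread

        if genes_path is None:
            raise InputError("MatrixMarket counts need a genes_path")
        mat = np.asarray(mmread(counts_path).todense())
        gene_ids = Path(genes_path).read_text().split()
        counts = pd.DataFrame(
            mat, index=pd.Index(gene_ids, name="gene_id"),
            columns=samples["sample_id"].tolist(),
        )
    else:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index.name = "gene_id"
    return counts, samples


def write_counts(
    counts: pd.DataFrame, samples: pd.DataFrame,
    counts_path: Union[str, Path], samples_path: Union[str, Path],
) -> None:
    if str(counts_path).endswith(".mtx"):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(counts_path), csr_matrix(counts.to_numpy()))
        Path(str(counts_path)[:-4] + ".genes.txt").write_text(
            "\n".join(map(str, counts.index)) + "\n"
        )
    else:
        counts.to_csv(counts_path, sep="\t")
    samples.to_csv(samples_path, sep="\t", index=False)


def _class_record(c: InteractionClass) -> dict:
    rec = {
        "response": c.response, "date_label": c.date_label,
        "category": c.category, "code": c.code, "mild": bool(c.mild),
        "delta_add": c.decomposition.delta_add,
        "delta_obs": c.decomposition.delta_obs,
        "beta_int": c.decomposition.beta_int,
    }
    if c.ratio is not None:
        rec.update(ratio=c.ratio.ratio, ci_low=c.ratio.ci_low,
                   ci_high=c.ratio.ci_high, ci_level=c.ratio.level,
                   scale=c.ratio.scale)
    else:
        rec.update(ratio=math.nan, ci_low=math.nan, ci_high=math.nan,
                   ci_level=math.nan, scale="")
    return rec


def _round6(x):
    if isinstance(x, float) and math.isfinite(x):
        return float(f"{x:.6g}")
    return x


def write_classification_report(
    classifications: Sequence[InteractionClass],
    path: Union[str, Path],
    format: str = "tsv",
    allow_empty: bool = False,
    summary: Optional[dict] = None,
) -> None:
    """Write classification outcomes as TSV or JSON (deterministic order).

    Records are sorted by (response, date_label); floats carry 6 significant
    digits.  ``summary`` (e.g. gene-type frequency proportions) is appended
    to JSON output under a ``summary`` key.
    """
    if not classifications and not allow_empty:
        raise InputError("no classifications to write (pass allow_empty=True to force)")
    records = sorted(
        (_class_record(c) for c in classifications),
        key=lambda r: (r["response"], r["date_label"]),
    )
    if format == "tsv":
        pd.DataFrame(records, columns=_REPORT_COLS).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )
    elif format == "json":
        payload = {"classifications": [
            {k: _round6(v) for k, v in r.items()} for r in records
        ]}
        if summary is not None:
            payload["summary"] = summary
        Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
    else:
        raise InputError(f"unknown report format {format!r}")


def read_classification_report(path: Union[str, Path], format: str = "tsv"):
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    return json.loads(Path(path).read_text())


def example_coefficients() -> List[StressorCoefficients]:
    """Packaged example coefficient table from a two-stressor field study.

    Season-wide and June fits of intertidal responses (barnacle abundance on
    a log link, grazer occurrence and macroalgal cover on logit links,
    microphytobenthos concentrations on the identity scale) under a 2x2
    warming x pollution design; intercepts were not reported and are NaN.
    """
    with resources.as_file(
        resources.files("multistress").joinpath("data/example_coefficients.tsv")
    ) as p:
        return read_coefficient_table(p)
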