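"""Tabular I/O, internal-standard normalization and matrix assembly.

Spot-volume tables are TSV files with columns
``gel_id, spot_id, channel, sample_id, volume``; the Cy2 internal-standard
rows carry ``sample_id = "POOL"``. Normalization divides every sample-channel
volume by the same-gel, same-spot Cy2 volume, which cancels multiplicative
gel effects exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError
from .syndata import StudyDesign

SPOT_COLUMNS = ["gel_id", "spot_id", "channel", "sample_id", "volume"]
CHANNELS = frozenset({"Cy2", "Cy3", "Cy5"})
POOL_ID = "POOL"


def write_spot_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for gel_id, table in tables.items():
        path = outdir / f"{gel_id}.tsv"
        table.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_spot_tables(paths) -> pd.DataFrame:
    """Read and validate spot-volume TSV files into one long table."""
    frames = []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype={
            "gel_id": str, "spot_id": str, "channel": str, "sample_id": str})
        missing = set(SPOT_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            if row.channel not in CHANNELS:
                raise FormatError(f"{path}:{i}: unknown channel {row.channel!r}")
            if not np.isfinite(row.volume) or row.volume <= 0:
                raise FormatError(f"{path}:{i}: non-positive volume {row.volume!r}")
        frames.append(df)
    if not frames:
        raise FormatError("no spot tables given")
    out = pd.concat(frames, ignore_index=True)
    dup = out.duplicated(subset=["gel_id", "spot_id", "channel", "sample_id"])
    if dup.any():
        row = out[dup].iloc[0]
        raise FormatError(
            f"duplicate record (gel={row.gel_id}, spot={row.spot_id}, "
            f"channel={row.channel}, sample={row.sample_id})")
    return out


def normalize_internal_standard(tables) -> pd.DataFrame:
    """Divide each sample-channel volume by the same-gel same-spot Cy2 volume.

    Returns a long table ``gel_id, spot_id, sample_id, ratio``. Spots lacking
    a Cy2 record on a gel are simply absent for that gel (missing).
    """
    if isinstance(tables, dict):
        long = pd.concat(tables.values(), ignore_index=True)
    else:
        long = tables
    if long.empty:
        raise AnalysisError("empty spot table: nothing to normalize")

    out = []
    for gel_id, gel in long.groupby("gel_id", sort=True):
        cy2 = gel[gel["channel"] == "Cy2"]
        if cy2.empty:
            raise FormatError(f"gel {gel_id} has no Cy2 internal-standard channel")
        std = cy2.set_index("spot_id")["volume"]
        if std.index.duplicated().any():
            raise FormatError(f"gel {gel_id} has duplicate Cy2 spots")
        samp = gel[gel["channel"] != "Cy2"]
        samp = samp[samp["spot_id"].isin(std.index)]
        ratio = samp["volume"].to_numpy() / std.loc[samp["spot_id"]].to_numpy()
        out.append(pd.DataFrame({
            "gel_id": samp["gel_id"].to_numpy(),
            "spot_id": samp["spot_id"].to_numpy(),
            "sample_id": samp["sample_id"].to_numpy(),
            "ratio": ratio,
        }))
    return pd.concat(out, ignore_index=True)


@dataclass
class ExpressionMatrix:
    """Log2-normalized abundances, features x samples, with class labels."""

    values: pd.DataFrame
    labels: pd.Series  # index: sample ids, values in {"tumor", "benign"}

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise AnalysisError("expression matrix contains non-finite values")
        if self.values.columns.duplicated().any():
            raise AnalysisError("duplicate sample ids")
        unlabeled = set(self.values.columns) - set(self.labels.index)
        if unlabeled:
            raise AnalysisError(f"samples without class label: {sorted(unlabeled)}")
        self.labels = self.labels.loc[self.values.columns]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def class_samples(self, cls: str) -> list[str]:
        return list(self.labels.index[self.labels == cls])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)].copy(),
                                self.labels.loc[list(sample_ids)].copy())

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.values.to_csv(prefix.with_suffix(".tsv"), sep="\t")
        prefix.with_suffix(".labels.json").write_text(
            json.dumps(self.labels.to_dict(), indent=1))

    @classmethod
    def read(cls, prefix: str | Path) -> "ExpressionMatrix":
        prefix = Path(prefix)
        values = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col=0)
        labels = pd.Series(json.loads(
            prefix.with_suffix(".labels.json").read_text()), name="class")
        return cls(values, labels)


def assemble_matrix(
    ratios: pd.DataFrame,
    design: StudyDesign,
    min_presence: float = 0.8,
) -> ExpressionMatrix:
    """Build the analysis matrix from normalized ratios.

    Failed samples are dropped, features observed in fewer than
    ``min_presence`` of the retained samples are removed, remaining missing
    cells are imputed with the feature median, and values are
    log2-transformed.
    """
    if ratios.empty:
        raise AnalysisError("empty ratio table: cannot assemble matrix")
    labels = design.labels()
    retained = [s for s in design.sample_ids if s in labels.index]

    wide = ratios.pivot_table(index="spot_id", columns="sample_id",
                              values="ratio", aggfunc="first")
    present = [s for s in retained if s in wide.columns]
    if len(present) < len(retained):
        lost = sorted(set(retained) - set(present))
        raise AnalysisError(f"retained samples with no measurements: {lost}")
    wide = wide[present]

    counts = labels.loc[present].value_counts()
    if counts.get("tumor", 0) < 2 or counts.get("benign", 0) < 2:
        raise AnalysisError("fewer than 2 samples in a class after exclusion")

    presence = wide.notna().mean(axis=1)
    wide = wide[presence >= min_presence]
    if wide.empty:
        raise AnalysisError("no features pass the presence filter")

    medians = wide.median(axis=1)
    wide = wide.apply(lambda row: row.fillna(medians[row.name]), axis=1)
    values = np.log2(wide)
    values.index.name = "spot_id"
    values.columns.name = None
    return ExpressionMatrix(values, labels.loc[present])


# ---------------------------------------------------------------------------
# clinical metadata

CLINICAL_COLUMNS = ["patient_id", "tumor_stage", "gleason", "hormone_therapy", "psa"]


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={
        "patient_id": str, "tumor_stage": str, "gleason": str,
        "hormone_therapy": str}, na_values=["NA"], keep_default_na=False)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df["psa"].notna() & (df["psa"] <= 0)
    if bad.any():
        raise FormatError(f"{path}: non-positive PSA for "
                          f"{df.loc[bad, 'patient_id'].tolist()}")
    return df


def load_clinical_table() -> pd.DataFrame:
    """Packaged 24-patient clinical metadata transcription."""
    with resources.as_file(resources.files("dige_biomarker.data")
                           .joinpath("clinical_table1.tsv")) as p:
        return read_clinical(p)


def load_tumor_group_table() -> pd.DataFrame:
    """Packaged transcription of the published tumor-group DE table."""
    with resources.as_file(resources.files("dige_biomarker.data")
                           .joinpath("tumor_group_table2.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def summarize_clinical(clinical: pd.DataFrame) -> dict:
    """Patient count, PSA mean/min/max over non-missing values, stage counts."""
    if clinical.empty:
        raise AnalysisError("empty clinical table")
    psa = clinical["psa"].dropna()
    summary = {
        "n_patients": int(len(clinical)),
        "n_psa": int(len(psa)),
        "psa_mean": round(float(psa.mean()), 2) if len(psa) else None,
        "psa_min": float(psa.min()) if len(psa) else None,
        "psa_max": float(psa.max()) if len(psa) else None,
        "stage_counts": clinical["tumor_stage"].dropna().value_counts().to_dict(),
    }
    return summary
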