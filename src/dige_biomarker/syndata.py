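"""Synthetic 2D-DIGE study generator.

Emulates the statistical structure of a tumor/benign DIGE experiment:
paired Cy3/Cy5 samples with dye swap on shared gels, a pooled Cy2 internal
standard, class signal carried by three latent factors plus a sparse direct
per-protein effect, a tumor subgroup, multiplicative gel/dye nuisance
effects, 1-3 gel spots per protein, and random missing spots.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

# per-stage RNG stream tags (seeded together with params.seed)
_TAG_DESIGN = 11
_TAG_EXPRESSION = 23
_TAG_SPOTS = 37

#: s.d. of the fixed per-spot multiplicative offset (log scale)
SPOT_OFFSET_SD = 0.4

#: baseline log-abundance distribution for proteins
BASELINE_MEAN = 7.0
BASELINE_SD = 1.0


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults emulate the 24+24-sample study design."""

    n_tumor: int = 24
    n_benign: int = 24
    n_failed_benign: int = 3
    subgroup_size: int = 10
    n_proteins: int = 79
    #: probability of a protein mapping to 1, 2 or 3 spots
    spots_per_protein: tuple[float, float, float] = (0.7, 0.2, 0.1)
    #: standardized shift of factor 1 for tumor samples
    factor_effect_a: float = 2.0
    #: standardized shift of factor 2 for the tumor subgroup
    factor_effect_b: float = 2.0
    #: s.d. of factor values within the tumor subgroup (< 1 makes the
    #: subgroup a tight cluster of very similar samples)
    subgroup_factor_sd: float = 0.3
    #: s.d. of per-protein factor loadings
    loading_scale: float = 0.5
    #: residual s.d. on the (natural) log scale
    noise_sd: float = 0.3
    #: fraction of proteins carrying a direct class effect
    frac_direct_de: float = 0.15
    #: magnitude of the direct class effect, natural log scale (>= log 1.5);
    #: sized so the synthetic signal reaches paper-scale classifier accuracy
    direct_log_fc: float = math.log(8.0)
    gel_effect_sd: float = 0.2
    dye_effect_sd: float = 0.1
    #: per-spot-per-gel probability of a missing measurement
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_benign", "n_proteins"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive count")
        if self.n_failed_benign < 0:
            raise ParameterError("n_failed_benign must be non-negative")
        if self.subgroup_size < 0 or self.subgroup_size > self.n_tumor:
            raise ParameterError("subgroup_size must be in [0, n_tumor]")
        # >= 2 retained samples per class is enforced at matrix assembly,
        # where the t-tests that need it happen; the generator itself only
        # requires that some benign sample survives
        if self.n_benign - self.n_failed_benign < 1:
            raise ParameterError("n_failed_benign leaves no benign samples")
        probs = self.spots_per_protein
        if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ParameterError("spots_per_protein must be 3 probabilities summing to 1")
        for name in ("loading_scale", "noise_sd", "gel_effect_sd",
                     "dye_effect_sd", "subgroup_factor_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ParameterError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.frac_direct_de <= 1.0:
            raise ParameterError("frac_direct_de must be in [0, 1]")
        if self.direct_log_fc < 0:
            raise ParameterError("direct_log_fc must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spots_per_protein"] = list(self.spots_per_protein)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticParams":
        d = dict(d)
        if "spots_per_protein" in d:
            d["spots_per_protein"] = tuple(d["spots_per_protein"])
        return cls(**d)


#: columns of the design table
DESIGN_COLUMNS = ["sample_id", "class", "subgroup", "failed", "gel_id", "dye"]


@dataclass
class StudyDesign:
    """Sample sheet: one row per sample with gel/dye assignment and flags."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(DESIGN_COLUMNS) - set(self.table.columns)
        if missing:
            raise ParameterError(f"design table lacks columns {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[~self.table["failed"]]

    def labels(self) -> pd.Series:
        """Class label per retained sample."""
        r = self.retained
        return pd.Series(r["class"].values, index=r["sample_id"].values, name="class")

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "StudyDesign":
        t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gel_id": str})
        t["subgroup"] = t["subgroup"].astype(bool)
        t["failed"] = t["failed"].astype(bool)
        return cls(t)


@dataclass
class GroundTruth:
    """Everything the generator knows, for parameter-recovery tests."""

    baseline: pd.Series            # per-protein mean log abundance
    loadings: pd.DataFrame         # proteins x 3
    direct_effects: pd.Series      # per-protein class effect (log scale)
    factors: pd.DataFrame          # 3 x samples
    true_matrix: pd.DataFrame      # proteins x samples, noise-free part + noise
    noise_free: pd.DataFrame       # proteins x samples, before noise
    spot_map: pd.DataFrame = field(default=None)  # spot_id, protein_id, offset

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.true_matrix.to_csv(outdir / "true_matrix.tsv", sep="\t")
        self.noise_free.to_csv(outdir / "noise_free.tsv", sep="\t")
        self.loadings.to_csv(outdir / "loadings.tsv", sep="\t")
        self.factors.to_csv(outdir / "factors.tsv", sep="\t")
        if self.spot_map is not None:
            self.spot_map.to_csv(outdir / "spot_map.tsv", sep="\t", index=False)
        meta = {
            "baseline": self.baseline.to_dict(),
            "direct_effects": self.direct_effects.to_dict(),
        }
        (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=1))


def generate_design(params: SyntheticParams) -> StudyDesign:
    """Assign samples to gels with alternating Cy3/Cy5 dye swap.

    One tumor and one benign sample share a gel where possible; leftover
    samples (unequal class sizes) get single-sample gels. Exactly
    ``n_failed_benign`` benign samples are flagged as labeling failures.
    """
    rng = np.random.default_rng([params.seed, _TAG_DESIGN])
    tumors = [f"T{i + 1:02d}" for i in range(params.n_tumor)]
    benigns = [f"B{i + 1:02d}" for i in range(params.n_benign)]

    subgroup = set(rng.choice(tumors, size=params.subgroup_size, replace=False))
    failed = set(rng.choice(benigns, size=params.n_failed_benign, replace=False))

    rows = []
    n_pair = min(params.n_tumor, params.n_benign)
    gel = 0
    for i in range(n_pair):
        gid = f"G{gel + 1:02d}"
        tumor_dye, benign_dye = ("Cy3", "Cy5") if gel % 2 == 0 else ("Cy5", "Cy3")
        rows.append((tumors[i], "tumor", tumors[i] in subgroup, False, gid, tumor_dye))
        rows.append((benigns[i], "benign", False, benigns[i] in failed, gid, benign_dye))
        gel += 1
    for s in tumors[n_pair:]:
        gid = f"G{gel + 1:02d}"
        rows.append((s, "tumor", s in subgroup, False, gid, "Cy3" if gel % 2 == 0 else "Cy5"))
        gel += 1
    for s in benigns[n_pair:]:
        gid = f"G{gel + 1:02d}"
        rows.append((s, "benign", False, s in failed, gid, "Cy3" if gel % 2 == 0 else "Cy5"))
        gel += 1

    table = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    return StudyDesign(table)


def generate_expression(
    design: StudyDesign, params: SyntheticParams
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the true per-protein log-abundance matrix.

    x[j, s] = mu_j + sum_k l[j,k] f[k,s] + delta_j * 1[tumor] + eps[j,s]
    with factor 1 shifted by ``factor_effect_a`` for tumors and factor 2 by
    ``factor_effect_b`` for the tumor subgroup; factor 3 is pure noise.
    """
    rng = np.random.default_rng([params.seed, _TAG_EXPRESSION])
    t = design.table
    samples = list(t["sample_id"])
    n = len(samples)
    p = params.n_proteins
    proteins = [f"P{j + 1:03d}" for j in range(p)]

    is_tumor = (t["class"] == "tumor").to_numpy()
    in_subgroup = t["subgroup"].to_numpy()

    mu = BASELINE_MEAN + BASELINE_SD * rng.standard_normal(p)
    loadings = params.loading_scale * rng.standard_normal((p, 3))

    factors = rng.standard_normal((3, n))
    # subgroup samples are "very similar": their factor noise is shrunk
    # toward the subgroup centroid
    factors[:, in_subgroup] *= params.subgroup_factor_sd
    factors[0] += params.factor_effect_a * is_tumor
    factors[1] += params.factor_effect_b * in_subgroup

    n_direct = round(params.frac_direct_de * p)
    delta = np.zeros(p)
    if n_direct > 0:
        idx = rng.choice(p, size=n_direct, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_direct)
        delta[idx] = signs * params.direct_log_fc

    noise_free = mu[:, None] + loadings @ factors + np.outer(delta, is_tumor)
    x = noise_free + params.noise_sd * rng.standard_normal((p, n))

    truth = GroundTruth(
        baseline=pd.Series(mu, index=proteins, name="baseline"),
        loadings=pd.DataFrame(loadings, index=proteins, columns=["f1", "f2", "f3"]),
        direct_effects=pd.Series(delta, index=proteins, name="direct"),
        factors=pd.DataFrame(factors, index=["f1", "f2", "f3"], columns=samples),
        true_matrix=pd.DataFrame(x, index=proteins, columns=samples),
        noise_free=pd.DataFrame(noise_free, index=proteins, columns=samples),
    )
    return truth.true_matrix, truth


def expand_to_spots(
    true_matrix: pd.DataFrame,
    design: StudyDesign,
    params: SyntheticParams,
    truth: GroundTruth | None = None,
) -> dict[str, pd.DataFrame]:
    """Expand proteins to 1-3 gel spots and emit per-gel volume tables.

    Sample-channel volume is exp(x + spot offset + gel effect + dye effect).
    The Cy2 internal standard on every gel carries the pooled mean over all
    non-failed samples. Missing (gel, spot) cells are dropped at
    ``missing_rate`` across all channels of that gel.
    """
    if not np.isfinite(true_matrix.to_numpy()).all():
        raise ParameterError("true_matrix contains non-finite values")
    rng = np.random.default_rng([params.seed, _TAG_SPOTS])
    t = design.table
    p = true_matrix.shape[0]

    mult = rng.choice([1, 2, 3], size=p, p=list(params.spots_per_protein))
    spot_rows = []
    for j, protein in enumerate(true_matrix.index):
        for _ in range(mult[j]):
            spot_rows.append((f"S{len(spot_rows) + 1:03d}", protein,
                              SPOT_OFFSET_SD * rng.standard_normal()))
    spot_map = pd.DataFrame(spot_rows, columns=["spot_id", "protein_id", "offset"])
    if truth is not None:
        truth.spot_map = spot_map

    gels = list(dict.fromkeys(t["gel_id"]))
    gel_effect = dict(zip(gels, params.gel_effect_sd * rng.standard_normal(len(gels))))
    dye_effect = {
        (g, c): params.dye_effect_sd * rng.standard_normal()
        for g in gels for c in ("Cy2", "Cy3", "Cy5")
    }

    # pooled internal standard: mean over non-failed samples only
    retained = design.retained["sample_id"].tolist()
    pool = true_matrix[retained].mean(axis=1)

    x = true_matrix
    tables: dict[str, pd.DataFrame] = {}
    for gid in gels:
        on_gel = t[t["gel_id"] == gid]
        keep = rng.random(len(spot_map)) >= params.missing_rate
        rows = []
        for _, spot in spot_map[keep].iterrows():
            sid, protein, off = spot["spot_id"], spot["protein_id"], spot["offset"]
            rows.append((gid, sid, "Cy2", "POOL",
                         math.exp(pool[protein] + off + gel_effect[gid]
                                  + dye_effect[(gid, "Cy2")])))
            for _, s in on_gel.iterrows():
                rows.append((gid, sid, s["dye"], s["sample_id"],
                             math.exp(x.at[protein, s["sample_id"]] + off
                                      + gel_effect[gid] + dye_effect[(gid, s["dye"])])))
        tables[gid] = pd.DataFrame(
            rows, columns=["gel_id", "spot_id", "channel", "sample_id", "volume"]
        )
    return tables


def generate_study(
    params: SyntheticParams,
) -> tuple[StudyDesign, GroundTruth, dict[str, pd.DataFrame]]:
    """Convenience wrapper: design -> expression -> spot tables."""
    design = generate_design(params)
    x, truth = generate_expression(design, params)
    tables = expand_to_spots(x, design, params, truth)
    return design, truth, tables


def write_clinical_fixture(path: str | Path) -> Path:
    """Write the packaged 24-patient clinical metadata table to ``path``."""
    path = Path(path)
    text = resources.files("dige_biomarker.data").joinpath(
        "clinical_table1.tsv").read_text()
    path.write_text(text)
    return path
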