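"""Synthetic cohort generator.

Emulates the statistical structure of a matched case-control urine
metabolomics study: log-normal metabolite peak areas with per-metabolite
location and spread, group differences planted on named marker metabolites as
standardized log-scale shifts d·σ, multiplicative per-sample dilution driven
by fluid intake (mirrored in urine osmolality), and demographics drawn from
the published group means/SDs. Everything is deterministic given the seed.

The generator makes no attempt to model mass-spectral peak shapes, retention
times, missingness, or limits of detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_PARITY_MEAN,
    EARLY_PANEL,
    GROUP_CASE,
    GROUP_CONTROL,
    MARKER_PATHWAYS,
    REFERENCE_OSMOLALITY,
    SyntheticConfig,
)
from .errors import ConfigurationError
from .normalize import MetaboliteMatrix

# Raw-scale heterogeneity: per-metabolite log-mean uniform over a wide
# abundance range, log-SD uniform over a realistic fold-change range. The
# analysis is invariant to these choices (median scaling removes location);
# heterogeneity is kept to stress the normalization.
_LOG_MEAN_RANGE = (np.log(1e4), np.log(1e7))
_LOG_SD_RANGE = (0.3, 1.0)

_RACES = np.array(["White", "Black", "Asian", "Other"])
_RACE_P = np.array([0.60, 0.15, 0.15, 0.10])
_ETHNICITIES = np.array(["Hispanic", "Non-Hispanic"])
_ETHNICITY_P = np.array([0.25, 0.75])

_GENERIC_PATHWAYS = (
    "Amino acid metabolism",
    "Lipid metabolism",
    "Carbohydrate metabolism",
    "Nucleotide metabolism",
    "Cofactor and vitamin metabolism",
    "Energy metabolism",
    "Peptide metabolism",
)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a synthetic cohort: the planted marker effects and the
    per-sample multiplicative dilution factors."""

    effects: dict[str, float]
    dilution: "pd.Series"

    def to_json(self, path) -> None:
        payload = {
            "effects": self.effects,
            "dilution": {k: float(v) for k, v in self.dilution.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _metabolite_names(config: SyntheticConfig) -> list[str]:
    """Endogenous column names: planted markers first, then the fixed
    early-panel metabolites (as null columns when unplanted), then generic ids."""
    names = list(config.planted_markers)
    for met in EARLY_PANEL:
        if met not in names:
            names.append(met)
    if len(names) > config.n_metabolites:
        names = names[: config.n_metabolites]
    i = 0
    while len(names) < config.n_metabolites:
        i += 1
        cand = f"met_{i:04d}"
        if cand not in names:
            names.append(cand)
    if len(set(names)) != len(names):
        raise ConfigurationError("metabolite names must be unique")
    return names


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lower: float | None) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    if lower is not None:
        while True:
            bad = out < lower
            if not bad.any():
                break
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return out


def _demographics(
    rng: np.random.Generator, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.Series]:
    rows = []
    dilution_all = []
    for group, n in ((GROUP_CASE, config.n_cases), (GROUP_CONTROL, config.n_control_pool)):
        p = config.demog_params[group]
        age = _truncated_normal(rng, *p["age"], n, lower=16.0)
        bmi = _truncated_normal(rng, *p["bmi"], n, lower=15.0)
        ga1 = _truncated_normal(rng, *p["ga1"], n, lower=4.0)
        ga2 = _truncated_normal(rng, *p["ga2"], n, lower=24.0)  # late collection is >= 24 wk
        parity = rng.poisson(DEFAULT_PARITY_MEAN.get(group, 2.0), n)
        race = rng.choice(_RACES, size=n, p=_RACE_P)
        eth = rng.choice(_ETHNICITIES, size=n, p=_ETHNICITY_P)
        dilution = np.exp(rng.normal(0.0, config.dilution_sd, n))
        dilution_all.append(dilution)
        for i in range(n):
            rows.append(
                {
                    "id": f"{group}-{i + 1:03d}",
                    "group": group,
                    "age": round(float(age[i]), 1),
                    "bmi": round(float(bmi[i]), 1),
                    "ga1": round(float(ga1[i]), 1),
                    "ga2": round(float(ga2[i]), 1),
                    "parity": int(parity[i]),
                    "race": str(race[i]),
                    "ethnicity": str(eth[i]),
                    "osmolality": round(float(REFERENCE_OSMOLALITY * dilution[i]), 2),
                }
            )
    subjects = pd.DataFrame(rows).set_index("id", drop=False)
    subjects.index.name = None
    dilution = pd.Series(np.concatenate(dilution_all), index=subjects["id"].to_numpy())
    return subjects, dilution


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, MetaboliteMatrix, PlantedTruth]:
    """Draw one synthetic cohort.

    Returns
    -------
    subjects : DataFrame
        One row per gravida (cases then control pool) with demographics and
        urine osmolality.
    matrix : MetaboliteMatrix
        Raw peak areas (samples × metabolites) with annotations; for controls
        the log value of metabolite m is Normal(μ_m, σ_m); for cases, planted
        markers are shifted by d·σ_m; raw area = exp(log value) × dilution.
    truth : PlantedTruth
        Planted effects and the true per-sample dilution factors.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    subjects, dilution = _demographics(rng, config)
    n_samples = len(subjects)
    names = _metabolite_names(config)
    p = len(names)

    mu = rng.uniform(*_LOG_MEAN_RANGE, p)
    sigma = rng.uniform(*_LOG_SD_RANGE, p)
    log_values = rng.normal(0.0, 1.0, (n_samples, p))

    planted_idx = {names.index(m) for m in config.planted_markers if m in names}
    if config.correlated_block > 0 and config.block_correlation > 0:
        rho = config.block_correlation
        free = [j for j in range(p) if j not in planted_idx][: config.correlated_block]
        shared = rng.normal(0.0, 1.0, n_samples)
        for j in free:
            log_values[:, j] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * log_values[:, j]

    log_values = mu[None, :] + sigma[None, :] * log_values

    is_case = (subjects["group"] == GROUP_CASE).to_numpy()
    for name, d in config.planted_markers.items():
        j = names.index(name)
        log_values[is_case, j] += d * sigma[j]

    raw = np.exp(log_values) * dilution.to_numpy()[:, None]

    # Non-endogenous columns for exercising the annotation filter
    extra_names, extra_cats = [], []
    for prefix, n_extra, cat in (
        ("xeno", config.n_xenobiotics, "xenobiotic"),
        ("partial", config.n_partially_characterized, "partially_characterized"),
    ):
        for i in range(n_extra):
            extra_names.append(f"{prefix}_{i + 1:03d}")
            extra_cats.append(cat)
    if extra_names:
        mu_x = rng.uniform(*_LOG_MEAN_RANGE, len(extra_names))
        sd_x = rng.uniform(*_LOG_SD_RANGE, len(extra_names))
        raw_x = np.exp(rng.normal(mu_x, sd_x, (n_samples, len(extra_names))))
        raw_x *= dilution.to_numpy()[:, None]
        raw = np.hstack([raw, raw_x])

    all_names = names + extra_names
    values = pd.DataFrame(raw, index=subjects["id"].to_numpy(), columns=all_names)

    pathways = [
        MARKER_PATHWAYS.get(m, _GENERIC_PATHWAYS[k % len(_GENERIC_PATHWAYS)])
        for k, m in enumerate(names)
    ] + ["Xenobiotic or uncharacterized"] * len(extra_names)
    annotations = pd.DataFrame(
        {
            "metabolite": all_names,
            "category": ["endogenous"] * p + extra_cats,
            "pathway": pathways,
        }
    ).set_index("metabolite")

    matrix = MetaboliteMatrix(values=values, annotations=annotations, state="raw")
    truth = PlantedTruth(effects=dict(config.planted_markers), dilution=dilution)
    return subjects, matrix, truth


def write_cohort(
    outdir,
    subjects: pd.DataFrame,
    matrix: MetaboliteMatrix,
    truth: PlantedTruth | None = None,
) -> dict[str, Path]:
    """Write the pipeline input CSVs (plus a truth JSON when available)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": outdir / "subjects.csv",
        "matrix": outdir / "metabolites.csv",
        "annotations": outdir / "annotations.csv",
    }
    subjects.to_csv(paths["subjects"], index=False)
    matrix.values.rename_axis("sample_id").to_csv(paths["matrix"])
    matrix.annotations.to_csv(paths["annotations"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    return paths
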