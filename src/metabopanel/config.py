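"""Study constants and the synthetic-cohort configuration.

The default configuration reproduces the design of the late-pregnancy GDM
urine-metabolomics study this package models: 46 GDM cases drawn against a
three-fold control pool, 626 endogenous metabolites, and eight consensus
marker metabolites planted at their published standardized log-scale effect
sizes d = (mean GDM − mean CON) / pooled SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigurationError

#: Published standardized effect sizes (GDM − CON, in pooled-SD units on the
#: natural-log scale) of the eight consensus late-pregnancy marker metabolites.
CONSENSUS_MARKER_EFFECTS: dict[str, float] = {
    "3-hydroxybutyrate": 0.815,
    "homocarnosine": -0.663,
    "1,5-anhydroglucitol": -0.383,
    "3-hydroxydodecanedioate": 0.759,
    "3-hydroxybutyrylcarnitine": 0.628,
    "3-methylhexanoylcarnitine": 0.673,
    "saccharopine": 0.822,
    "acetylcholine": 0.704,
}

#: Functional pathway annotation of the consensus markers.
MARKER_PATHWAYS: dict[str, str] = {
    "3-hydroxybutyrate": "Fatty acid catabolism",
    "homocarnosine": "GABA metabolism antioxidant",
    "1,5-anhydroglucitol": "Glucose competitor for renal tubular transport",
    "3-hydroxydodecanedioate": "Medium chain fatty acid catabolism",
    "3-hydroxybutyrylcarnitine": "Fatty acid catabolism",
    "3-methylhexanoylcarnitine": "Fatty acid metabolism",
    "saccharopine": "Lysine catabolism",
    "acetylcholine": "Choline metabolism neurotransmitter",
}

#: The eight consensus metabolites: default feature panel for the
#: late-pregnancy classification tree.
LATE_PANEL: tuple[str, ...] = tuple(CONSENSUS_MARKER_EFFECTS)

#: The four metabolites the final published late-pregnancy tree actually used.
LATE_FINAL_TREE_METABOLITES: tuple[str, ...] = (
    "3-hydroxybutyrate",
    "1,5-anhydroglucitol",
    "homocarnosine",
    "3-hydroxydodecanedioate",
)

#: The seven-metabolite first-trimester model panel, reused as a fixed feature
#: list for the early-panel comparison tree.
EARLY_PANEL: tuple[str, ...] = (
    "dihydroorotate",
    "phenol glucuronide",
    "nicotinate ribonucleoside",
    "saccharopine",
    "lanthionine",
    "argininate",
    "7,8-dihydroneopterin",
)

#: Demographic means/SDs by group: age (years), pre-pregnancy BMI (kg/m²),
#: gestational age at the early (GA1) and late (GA2, ≥24 wk) collections (weeks).
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, tuple[float, float]]] = {
    "GDM": {"age": (32.0, 4.7), "bmi": (31.5, 6.8), "ga1": (12.0, 2.9), "ga2": (30.8, 3.6)},
    "CON": {"age": (31.8, 4.2), "bmi": (29.9, 6.3), "ga1": (12.0, 2.9), "ga2": (30.5, 3.0)},
}

#: Mean parity by group (drawn as Poisson counts).
DEFAULT_PARITY_MEAN = {"GDM": 2.5, "CON": 1.9}

GROUP_CASE = "GDM"
GROUP_CONTROL = "CON"

#: Reference urine osmolality (mOsm/kg) multiplying the simulated dilution factor.
REFERENCE_OSMOLALITY = 500.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_cases, n_control_pool : int
        Number of GDM cases and size of the candidate control pool
        (``n_control_pool >= n_cases``).
    n_metabolites : int
        Number of endogenous metabolite columns.
    planted_markers : dict[str, float]
        Metabolite name -> standardized log-scale effect size d planted for
        cases. Unlisted metabolites are identically distributed in both groups.
    demog_params : dict
        Per-group ``{var: (mean, sd)}`` for age, bmi, ga1, ga2.
    dilution_sd : float
        SD of the log multiplicative per-sample dilution (fluid-intake) factor.
    seed : int
        Generator seed; identical seeds give bit-identical cohorts.
    n_xenobiotics, n_partially_characterized : int
        Extra non-endogenous columns appended after the endogenous block, for
        exercising the annotation filter.
    correlated_block, block_correlation : int, float
        Optional equicorrelated block among the first ``correlated_block``
        non-planted metabolites (off by default: the generator assumes
        metabolite independence given group).
    """

    n_cases: int = 46
    n_control_pool: int = 138
    n_metabolites: int = 626
    planted_markers: dict[str, float] = field(
        default_factory=lambda: dict(CONSENSUS_MARKER_EFFECTS)
    )
    demog_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            g: dict(v) for g, v in DEFAULT_DEMOGRAPHICS.items()
        }
    )
    dilution_sd: float = 0.3
    seed: int = 0
    n_xenobiotics: int = 0
    n_partially_characterized: int = 0
    correlated_block: int = 0
    block_correlation: float = 0.0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_control_pool <= 0 or self.n_metabolites <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_control_pool < self.n_cases:
            raise ConfigurationError(
                f"control pool ({self.n_control_pool}) must be >= cases ({self.n_cases})"
            )
        if len(self.planted_markers) > self.n_metabolites:
            raise ConfigurationError("more planted markers than metabolites")
        if self.dilution_sd < 0:
            raise ConfigurationError("dilution_sd must be >= 0")
        for group, params in self.demog_params.items():
            for var, (mean, sd) in params.items():
                if sd <= 0:
                    raise ConfigurationError(
                        f"demographic SD for {group}/{var} must be > 0, got {sd}"
                    )
        if not (0.0 <= self.block_correlation < 1.0):
            raise ConfigurationError("block_correlation must be in [0, 1)")
        if self.n_xenobiotics < 0 or self.n_partially_characterized < 0:
            raise ConfigurationError("non-endogenous column counts must be >= 0")


def default_paper_config(seed: int = 0) -> SyntheticConfig:
    """Configuration matching the published study design.

    46 cases, a 138-subject control pool, 626 endogenous metabolites, and the
    eight consensus markers planted at their published effect sizes.
    """
    cfg = SyntheticConfig(seed=seed)
    cfg.validate()
    return cfg


def config_to_yaml(config: SyntheticConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def config_from_yaml(path) -> SyntheticConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = SyntheticConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"invalid synthetic config: {exc}") from exc
    # YAML round-trips tuples as lists
    object.__setattr__(
        cfg,
        "demog_params",
        {g: {k: tuple(v) for k, v in p.items()} for g, p in cfg.demog_params.items()},
    )
    cfg.validate()
    return cfg
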