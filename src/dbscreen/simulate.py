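"""Synthetic DBS-proteome cohorts with known ground truth.

The generator emulates the structure of a dried-blood-spot screening
study so every downstream stage is testable without any measured data:

* log-normal protein abundances around per-protein baselines, anchored to
  an abundant, never-censored beta-actin row (the normalization anchor);
* newborn-vs-adult differential proteins via a per-protein log2 shift map
  (fetal-hemoglobin-like proteins up in newborns,
  coagulation/immunoglobulin-like proteins down);
* disease conditions that multiplicatively knock down a causative protein,
  optionally co-reduce interaction partners (a p22/p91-phox-like pair),
  and scale whole cell-population marker panels (T-cell / platelet /
  neutrophil) to model cytopenias;
* missing-not-at-random left-censoring below a detection limit drawn as a
  low quantile of the intensity distribution, plus a small random
  missingness rate.

The default cohort sizes are the study conditions: 40 healthy newborns and
8 healthy adults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .matrix import AbundanceMatrix, ValidationError, make_sample_meta
from .screen import DEFAULT_PANELS


@dataclass
class DiseaseSpec:
    """One simulated disease condition."""

    disease_name: str
    causative_protein: str
    knockdown_factor: float = 0.05
    n_samples: int = 1
    partner_proteins: dict[str, float] = field(default_factory=dict)
    panel_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        factors = [self.knockdown_factor, *self.partner_proteins.values(),
                   *self.panel_effects.values()]
        if any(not (0.0 <= f <= 1.0) for f in factors):
            raise ValidationError("knockdown/partner/panel factors must lie in [0, 1]")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")


@dataclass
class CohortConfig:
    """Everything the generator needs; the seed fully determines output."""

    n_proteins: int = 500
    n_newborn: int = 40
    n_adult: int = 8
    patient_specs: list[DiseaseSpec] = field(default_factory=list)
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 3.0
    noise_log2_sd: float = 0.5
    actb_protein_id: str = "ACTB"
    newborn_effect_map: dict[str, float] = field(default_factory=dict)
    named_proteins: list[str] = field(default_factory=list)
    panels: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_PANELS))
    lod_quantile: float = 0.05
    missing_rate_random: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_newborn, self.n_adult) < 0:
            raise ValidationError("counts must be >= 0")
        if not (0.0 <= self.lod_quantile < 1.0):
            raise ValidationError("lod_quantile must lie in [0, 1)")
        if not (0.0 <= self.missing_rate_random < 1.0):
            raise ValidationError("missing_rate_random must lie in [0, 1)")


@dataclass
class TruthTable:
    """Ground truth of a generated cohort."""

    effects: pd.DataFrame  # one row per injected effect
    lod_value: float
    censored: pd.DataFrame  # boolean protein x sample mask
    random_missing: pd.DataFrame  # boolean protein x sample mask

    @property
    def n_censored(self) -> int:
        return int(self.censored.to_numpy().sum())


def _protein_names(config: CohortConfig) -> tuple[list[str], int]:
    named = [config.actb_protein_id]
    for p in config.named_proteins:
        if p not in named:
            named.append(p)
    for spec in config.patient_specs:
        for p in (spec.causative_protein, *spec.partner_proteins):
            if p not in named:
                named.append(p)
        for panel in spec.panel_effects:
            if panel not in config.panels:
                raise ValidationError(
                    f"unknown panel {panel!r}; known: {sorted(config.panels)}"
                )
            for p in config.panels[panel]:
                if p not in named:
                    named.append(p)
    for p in config.newborn_effect_map:
        if p not in named:
            named.append(p)
    if len(named) > config.n_proteins:
        raise ValidationError(
            f"n_proteins={config.n_proteins} too small for {len(named)} named proteins"
        )
    generic = [f"P{i:04d}" for i in range(1, config.n_proteins - len(named) + 1)]
    return named + generic, len(named)


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[AbundanceMatrix, pd.DataFrame, TruthTable]:
    """Draw one cohort: (abundance matrix, sample metadata, ground truth)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    proteins, n_named = _protein_names(config)
    n_prot = len(proteins)
    prot_index = {p: i for i, p in enumerate(proteins)}

    samples: list[str] = []
    meta_records: list[dict] = []
    for i in range(config.n_newborn):
        sid = f"NB{i + 1:02d}"
        samples.append(sid)
        meta_records.append({"sample_id": sid, "group": "healthy_newborn"})
    for i in range(config.n_adult):
        sid = f"AD{i + 1:02d}"
        samples.append(sid)
        meta_records.append({"sample_id": sid, "group": "healthy_adult"})
    for spec in config.patient_specs:
        for i in range(spec.n_samples):
            sid = f"PT_{spec.disease_name}_{i + 1:02d}"
            samples.append(sid)
            meta_records.append(
                {
                    "sample_id": sid,
                    "group": "patient",
                    "disease": spec.disease_name,
                    "causative_gene": spec.causative_protein,
                    "onset_status": "post_onset",
                }
            )
    meta = make_sample_meta(meta_records)
    n_samp = len(samples)

    # baselines; named proteins (disease targets, partners, panel markers,
    # age-shifted proteins) model the screen's target class of consistently
    # quantifiable blood proteins, so they sit in the upper abundance range;
    # generic filler proteins span the full dynamic range and feed the
    # censoring/evidence-filter machinery
    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_prot)
    baselines[:n_named] = rng.uniform(
        config.baseline_log2_mean,
        config.baseline_log2_mean + 2.0 * config.baseline_log2_sd,
        n_named,
    )
    # the anchor sits well above everything so it never censors
    baselines[0] = config.baseline_log2_mean + 4.0 * config.baseline_log2_sd

    log2 = baselines[:, None] + rng.normal(0.0, config.noise_log2_sd, (n_prot, n_samp))

    effects = []
    # newborn-vs-adult physiological shifts
    nb_cols = np.array([meta.loc[s, "group"] == "healthy_newborn" for s in samples])
    for protein, shift in config.newborn_effect_map.items():
        log2[prot_index[protein], nb_cols] += shift
        effects.append(
            {"effect": "newborn_shift", "protein": protein,
             "target": "healthy_newborn", "log2_shift": shift}
        )

    # disease knockdowns (multiplicative on the linear scale)
    with np.errstate(divide="ignore"):
        for spec in config.patient_specs:
            cols = np.array(
                [meta.loc[s, "disease"] == spec.disease_name if meta.loc[s, "group"] == "patient"
                 else False for s in samples]
            )
            factor_map: dict[str, float] = {spec.causative_protein: spec.knockdown_factor}
            effects.append(
                {"effect": "knockdown", "protein": spec.causative_protein,
                 "target": spec.disease_name, "factor": spec.knockdown_factor}
            )
            for partner, f in spec.partner_proteins.items():
                factor_map[partner] = min(factor_map.get(partner, 1.0), f)
                effects.append(
                    {"effect": "partner", "protein": partner,
                     "target": spec.disease_name, "factor": f}
                )
            for panel, f in spec.panel_effects.items():
                for member in config.panels.get(panel, ()):
                    factor_map[member] = min(factor_map.get(member, 1.0), f)
                effects.append(
                    {"effect": "panel", "protein": panel,
                     "target": spec.disease_name, "factor": f}
                )
            for protein, f in factor_map.items():
                if protein not in prot_index:
                    raise ValidationError(f"effect on unknown protein {protein!r}")
                log2[prot_index[protein], cols] += np.log2(f) if f > 0 else -np.inf

    intensity = np.exp2(log2)  # factor 0 -> exact 0, below any positive LOD

    # MNAR left-censoring at a low quantile of the intensity distribution
    lod_value = (
        float(np.quantile(intensity, config.lod_quantile))
        if config.lod_quantile > 0
        else 0.0
    )
    censored = intensity < lod_value
    censored[0, :] = False  # the normalization anchor is never censored

    # sprinkle of random (MCAR) missingness on the generic background; the
    # named proteins model the screen's target class of consistently
    # quantified blood proteins, so they only go absent by LOD censoring
    random_missing = rng.random((n_prot, n_samp)) < config.missing_rate_random
    random_missing[:n_named, :] = False
    random_missing &= ~censored

    values = intensity.copy()
    values[censored | random_missing] = np.nan

    vdf = pd.DataFrame(values, index=pd.Index(proteins, name="protein"), columns=samples)
    ldf = pd.DataFrame(censored, index=vdf.index, columns=samples)
    mdf = pd.DataFrame(random_missing, index=vdf.index, columns=samples)
    peptides = pd.Series(
        rng.integers(2, 30, n_prot), index=vdf.index, name="peptides"
    )
    matrix = AbundanceMatrix(vdf, peptides, ldf)
    truth = TruthTable(pd.DataFrame(effects), lod_value, ldf.copy(), mdf)
    return matrix, meta, truth


def censor_below_lod(
    matrix: AbundanceMatrix, lod_value: float
) -> tuple[AbundanceMatrix, int]:
    """Censor every intensity strictly below ``lod_value``.

    Returns the censored matrix and the count of newly censored entries.
    """
    if lod_value < 0:
        raise ValidationError("lod_value must be >= 0")
    vals = matrix.intensities.copy()
    newly = vals.notna() & (vals < lod_value)
    vals[newly] = np.nan
    out = AbundanceMatrix(vals, matrix.peptide_counts.copy(), matrix.below_lod | newly)
    return out, int(newly.to_numpy().sum())


# ---------------------------------------------------------------------------
# bundled demo scenario
# ---------------------------------------------------------------------------

#: newborn-vs-adult physiological shifts (log2): fetal proteins up,
#: coagulation / immunoglobulin proteins down in newborns
DEMO_NEWBORN_EFFECTS: dict[str, float] = {
    "HBG1": 3.0,
    "HBG2": 3.0,
    "HBE1": 2.5,
    "AFP": 2.5,
    "SERPINC1": -1.5,
    "SERPIND1": -1.5,
    "PROC": -2.0,
    "HP": -1.5,
    "IGHM": -2.5,
    "JCHAIN": -2.0,
}

#: granule / secondary-marker proteins used by the demo diseases
DEMO_MARKER_PROTEINS = ["CTSG", "MPO", "ELANE", "RAB27B", "UNC13D", "CYBB",
                        "CYBA", "WAS", "BTK", "STXBP2", "STX11"]


def demo_disease_specs() -> list[DiseaseSpec]:
    """Three study-like disease conditions with distinct secondary effects."""
    return [
        # Wiskott-Aldrich-like: causative loss plus thrombocytopenia; the
        # platelet-borne granule proteins Rab27b and Munc13-4 co-reduce
        # with the platelet count
        DiseaseSpec(
            "WASlike", "WAS", knockdown_factor=0.05, n_samples=5,
            partner_proteins={"RAB27B": 0.3, "UNC13D": 0.3},
            panel_effects={"platelet": 0.2},
        ),
        # SCID-like: T-cell lymphopenia dominates
        DiseaseSpec(
            "SCIDlike", "BTK", knockdown_factor=0.05, n_samples=4,
            panel_effects={"t_cell": 0.1},
        ),
        # CGD-like: causative loss co-reducing its membrane partner
        DiseaseSpec(
            "CGDlike", "CYBB", knockdown_factor=0.05, n_samples=3,
            partner_proteins={"CYBA": 0.2},
        ),
    ]


def null_config(seed: int = 0, n_proteins: int = 300) -> CohortConfig:
    """Sampling-noise-only null cohort: no injected effects, no censoring.

    This is the global null for checking error control of the testing
    machinery itself; the MNAR censoring + downshift-imputation path is
    deliberately off, because downshifted imputed values are *designed* to
    surface as reductions and are exercised by the effect-recovery checks
    instead.
    """
    return CohortConfig(
        n_proteins=n_proteins,
        lod_quantile=0.0,
        missing_rate_random=0.0,
        seed=seed,
    )


def demo_config(seed: int = 0, n_proteins: int = 500) -> CohortConfig:
    """Study-shaped demo cohort: 40 newborns, 8 adults, 3 diseases."""
    panel_members = [p for members in DEFAULT_PANELS.values() for p in members]
    return CohortConfig(
        n_proteins=n_proteins,
        patient_specs=demo_disease_specs(),
        newborn_effect_map=dict(DEMO_NEWBORN_EFFECTS),
        named_proteins=(
            list(DEMO_MARKER_PROTEINS) + list(DEMO_NEWBORN_EFFECTS) + panel_members
        ),
        seed=seed,
    )


def demo_gene_sets(n_filler: int = 15, set_size: int = 12, seed: int = 99) -> GeneSetCollection:
    """Small pathway collection matching the demo protein names.

    Real panels (platelet / T-cell / neutrophil biology) plus random filler
    sets over the generic proteins so enrichment has a background to rank
    against.
    """
    rng = np.random.default_rng(seed)
    sets = {
        "HEMOSTASIS": ["ITGA2B", "GP1BA", "RAB27B", "UNC13D", "PROC",
                       "SERPINC1", "SERPIND1"],
        "T_CELL_RECEPTOR": ["CD2", "CD3D", "CD3E", "CD5", "CD247"],
        "NEUTROPHIL_DEGRANULATION": ["ITGAM", "ITGB2", "CD33", "CEACAM8",
                                     "CTSG", "MPO", "ELANE", "CYBA", "CYBB"],
        "HEMOGLOBIN_COMPLEX": ["HBG1", "HBG2", "HBE1"],
        "COMPLEMENT_AND_COAGULATION": ["SERPINC1", "SERPIND1", "PROC", "HP"],
    }
    for i in range(n_filler):
        members = [f"P{j:04d}" for j in rng.choice(np.arange(1, 400), set_size, replace=False)]
        sets[f"FILLER_{i + 1:02d}"] = members
    descriptions = {name: "demo gene set" for name in sets}
    return GeneSetCollection(sets, descriptions)
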