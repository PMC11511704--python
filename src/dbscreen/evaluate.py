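"""Monte-Carlo evaluation of the screening pipeline on synthetic cohorts.

Two experiment families:

* ``null_false_discovery`` — global-null cohorts (no injected effects, no
  censoring) quantify the error control of the DEP stage: the false
  discovery proportion of the adaptive two-stage procedure at its alpha,
  and the fraction of proteins the q/fold-change cutoffs call.
* ``knockdown_recovery`` — disease cohorts with a known causative-protein
  knockdown plus a T-cell panel reduction quantify screening power: the
  per-sample deficiency flag, the causative protein's rank among
  down-regulated proteins, specificity on healthy samples, and recovery of
  the panel analogue (CD3E) through the dual-control marker procedure.

Cohort sizes follow the study design (40 healthy newborns, 8 healthy
adults, a handful of patients per disease).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import DepConfig, dep_table
from .enrichment import MarkerConfig, dual_control_markers
from .matrix import NormalizedMatrix
from .preprocess import (
    ImputeParams,
    filter_by_evidence,
    impute_downshift,
    log2_transform,
    normalize_actb,
)
from .screen import ReferenceIntervalScreen, compute_reference
from .simulate import (
    CohortConfig,
    DiseaseSpec,
    demo_gene_sets,
    generate_cohort,
    null_config,
)


def _preprocess(matrix, newborns, seed):
    filtered = filter_by_evidence(matrix, 2, newborns)
    logged = log2_transform(normalize_actb(filtered))
    return impute_downshift(logged, ImputeParams(seed=seed))


def null_false_discovery(
    n_seeds: int = 500,
    alpha: float = 0.05,
    n_proteins: int = 300,
    base_seed: int = 0,
) -> dict:
    """Mean false-discovery proportion of the DEP stage under the global
    null (newborn vs adult, no injected effects, no censoring).

    Every discovery is false by construction, so the per-seed FDP is
    V / max(R, 1) with V = R; the returned means estimate the FDR of the
    two-stage procedure at ``alpha`` and the rate of q/fold-change DEP
    calls.
    """
    config = DepConfig(alpha_bky=alpha)
    fdps, dep_fractions = [], []
    for i in range(n_seeds):
        seed = (base_seed + i) % 2**31
        matrix, meta, _ = generate_cohort(null_config(seed=seed, n_proteins=n_proteins))
        newborns = list(meta.index[meta["group"] == "healthy_newborn"])
        adults = list(meta.index[meta["group"] == "healthy_adult"])
        imputed = _preprocess(matrix, newborns, seed)
        deps = dep_table(imputed.values, newborns, adults, config)
        r = int(deps["significant"].sum())
        fdps.append(r / max(r, 1) if r else 0.0)
        dep_fractions.append(deps["is_dep"].mean())
    return {
        "n_seeds": n_seeds,
        "mean_fdp": float(np.mean(fdps)),
        "mean_dep_fraction": float(np.mean(dep_fractions)),
    }


@dataclass
class RecoveryResult:
    """Per-seed outcomes of the knockdown-recovery experiment."""

    flagged_all_patients: list[bool]
    patient_flag_rate: list[float]
    marker_hit: list[bool]
    healthy_specificity: list[float]

    @property
    def n_seeds(self) -> int:
        return len(self.flagged_all_patients)

    def rates(self) -> dict:
        return {
            "n_seeds": self.n_seeds,
            "flag_sensitivity": float(np.mean(self.patient_flag_rate)),
            "all_patients_flagged_rate": float(np.mean(self.flagged_all_patients)),
            "marker_recovery": float(np.mean(self.marker_hit)),
            "healthy_specificity": float(np.mean(self.healthy_specificity)),
        }


def _recovery_config(seed: int, n_proteins: int, knockdown: float, n_patients: int):
    return CohortConfig(
        n_proteins=n_proteins,
        patient_specs=[
            DiseaseSpec(
                "SCIDlike",
                "TARGET",
                knockdown_factor=knockdown,
                n_samples=n_patients,
                panel_effects={"t_cell": 0.1},
            )
        ],
        seed=seed,
    )


def knockdown_recovery(
    n_seeds: int = 100,
    knockdown: float = 0.1,
    n_patients: int = 5,
    n_proteins: int = 300,
    base_seed: int = 0,
    marker_gene: str = "CD3E",
) -> RecoveryResult:
    """Screening power on SCID-like cohorts with a known ground truth.

    Per seed: flag every patient's causative protein against the
    healthy-newborn reference (below-group-minimum rule; sensitivity is the
    per-sample flag rate), measure specificity of the flag on all healthy
    samples, and check that the T-cell panel analogue surfaces in the
    dual-control marker report.
    """
    flagged_all, flag_rate, marker_hits, specificity = [], [], [], []
    genesets = demo_gene_sets(seed=12345)
    dep_config = DepConfig()
    marker_config = MarkerConfig()
    for i in range(n_seeds):
        seed = (base_seed + i) % 2**31
        matrix, meta, _ = generate_cohort(
            _recovery_config(seed, n_proteins, knockdown, n_patients)
        )
        newborns = list(meta.index[meta["group"] == "healthy_newborn"])
        adults = list(meta.index[meta["group"] == "healthy_adult"])
        patients = list(meta.index[meta["group"] == "patient"])
        imputed = _preprocess(matrix, newborns, seed)
        linear = NormalizedMatrix(np.exp2(imputed.values))

        screen = ReferenceIntervalScreen().fit(linear, meta)
        ref_min = screen.reference_.table.loc["TARGET", "min"]
        censored = matrix.below_lod.loc["TARGET"]
        flags = {
            s: bool(censored[s]) or linear.values.loc["TARGET", s] < ref_min
            for s in linear.samples
        }
        flagged_all.append(all(flags[s] for s in patients))
        flag_rate.append(sum(flags[s] for s in patients) / len(patients))
        healthy = newborns + adults
        specificity.append(1.0 - sum(flags[s] for s in healthy) / len(healthy))

        deps_nb = dep_table(imputed.values, patients, newborns, dep_config)
        deps_ad = dep_table(imputed.values, patients, adults, dep_config)
        universe = list(imputed.proteins)
        report = dual_control_markers(
            deps_nb, deps_ad, genesets.restricted_to(universe), universe,
            marker_config,
        )
        marker_hits.append(marker_gene in set(report["marker"]))
    return RecoveryResult(flagged_all, flag_rate, marker_hits, specificity)


def top_ranked_knockdown(
    n_seeds: int = 200,
    knockdown: float = 0.05,
    n_patients: int = 5,
    n_proteins: int = 300,
    base_seed: int = 0,
) -> float:
    """Fraction of knockdown-only cohorts where the causative protein is
    the top-ranked down-regulated protein (rank: q ascending, then log2
    fold change ascending) in the patient-vs-newborn comparison."""
    hits = 0
    for i in range(n_seeds):
        seed = (base_seed + i) % 2**31
        config = CohortConfig(
            n_proteins=n_proteins,
            patient_specs=[
                DiseaseSpec("KO", "TARGET", knockdown_factor=knockdown,
                            n_samples=n_patients)
            ],
            seed=seed,
        )
        matrix, meta, _ = generate_cohort(config)
        newborns = list(meta.index[meta["group"] == "healthy_newborn"])
        patients = list(meta.index[meta["group"] == "patient"])
        imputed = _preprocess(matrix, newborns, seed)
        deps = dep_table(imputed.values, patients, newborns)
        down = deps[deps["direction"] == "down"].sort_values(
            ["q_value", "log2_fold_change"], kind="stable"
        )
        hits += len(down) > 0 and down.index[0] == "TARGET"
    return hits / n_seeds
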