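"""Seeded synthetic cell-line and patient cohorts.

Real inputs for this kind of analysis are large public RNA-seq compendia
(cell-line panels with literature subtype labels, and a tumour cohort
with survival endpoints).  This module generates cohorts with the same
statistical structure so every downstream stage can be exercised and
property-tested offline:

* two latent subtypes (A, B) with a configurable set of informative
  cassette exons whose latent PSI differs by |psi_a - psi_b|;
* Beta-distributed latent PSI per sample (mean = subtype mean,
  dispersion via a concentration parameter), binomial IC at Poisson
  total coverage, SC = coverage - IC;
* a patient-domain shift: each tumour mixes its subtype PSI toward a
  background PSI according to a Uniform tumour purity; "unassignable"
  patients have purity near zero and therefore sit at the background;
* log-normal TPM expression with a planted log2 fold change on a subset
  of genes, attenuated by purity in patients;
* exponential survival with a configurable hazard ratio between
  subtypes and independent uniform censoring.

One master seed spawns independent substreams for PSI, counts,
expression and survival, so each block is reproducible on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .splicing import EventCountTable

__all__ = ["CohortConfig", "SyntheticTruth", "Cohort", "generate_cohort", "write_fixture", "read_fixture"]


@dataclass
class CohortConfig:
    """Parameters of the synthetic world.

    Defaults mirror the scale of the analysis this package re-creates:
    a 12+12 labelled cell-line panel, 120 unlabelled patients with ~45%
    latent subtype B and ~13% unassignable (low-purity) tumours, 200
    cassette exons of which 30 are informative with |deltaPSI| = 0.4,
    and a planted subtype hazard ratio of 4.  Sequencing depth and PSI
    dispersion are not published quantities; the defaults (mean 100
    junction reads per event, Beta concentration 30) are realistic for
    pooled junction counts in bulk RNA-seq and are fully configurable.
    """

    n_cell_a: int = 12
    n_cell_b: int = 12
    n_patients: int = 120
    frac_patient_b: float = 0.45
    frac_unassignable: float = 0.13
    n_events: int = 200
    n_informative: int = 30
    psi_a: float = 0.8
    psi_b: float = 0.4
    psi_background: float = 0.6
    concentration: float = 30.0
    depth_mean: float = 100.0
    purity_range: tuple[float, float] = (0.6, 1.0)
    n_genes: int = 300
    n_de_genes: int = 50
    log2fc_effect: float = 2.0
    hazard_ratio_true: float = 4.0
    baseline_hazard: float = 0.04
    censor_horizon: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_events:
            raise ValueError("n_informative must be <= n_events")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must be <= n_genes")
        for name in ("psi_a", "psi_b", "psi_background", "frac_patient_b", "frac_unassignable"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("purity_range must satisfy 0 <= lo <= hi <= 1")
        if min(self.n_cell_a, self.n_cell_b) < 1:
            raise ValueError("each cell-line subtype group must be non-empty")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name in ("concentration", "depth_mean", "hazard_ratio_true", "baseline_hazard", "censor_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    labels: pd.Series              # per sample: A / B / unassignable
    informative_event_ids: list[str]
    de_gene_ids: list[str]
    purity: pd.Series              # per patient
    true_hazard_ratio: float

    def equals(self, other: "SyntheticTruth") -> bool:
        return (
            self.labels.equals(other.labels)
            and self.informative_event_ids == other.informative_event_ids
            and self.de_gene_ids == other.de_gene_ids
            and self.purity.equals(other.purity)
            and self.true_hazard_ratio == other.true_hazard_ratio
        )


@dataclass
class Cohort:
    """All tables of one synthetic cohort."""

    cells: EventCountTable
    patients: EventCountTable
    expression: pd.DataFrame       # genes x samples, TPM
    annotation: pd.DataFrame       # sample_id index: domain, subtype
    survival: pd.DataFrame         # sample_id index: time (years), event, endpoint
    truth: SyntheticTruth

    def equals(self, other: "Cohort") -> bool:
        return (
            self.cells.equals(other.cells)
            and self.patients.equals(other.patients)
            and self.expression.equals(other.expression)
            and self.annotation.equals(other.annotation)
            and self.survival.equals(other.survival)
            and self.truth.equals(other.truth)
        )


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    mean = min(max(mean, 1e-6), 1.0 - 1e-6)
    return mean * concentration, (1.0 - mean) * concentration


def _event_frame(n_events: int) -> pd.DataFrame:
    ids = [f"ev{i + 1:04d}" for i in range(n_events)]
    return pd.DataFrame(
        {
            "gene": [f"G{i + 1:04d}" for i in range(n_events)],
            "chrom": [f"chr{(i % 22) + 1}" for i in range(n_events)],
            "start": [10_000 * (i + 1) + 1 for i in range(n_events)],
            "end": [10_000 * (i + 1) + 150 for i in range(n_events)],
            "strand": ["+" if i % 2 == 0 else "-" for i in range(n_events)],
        },
        index=pd.Index(ids, name="event_id"),
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort from the stated generative model."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_psi, rng_counts, rng_expr, rng_surv = [np.random.default_rng(s) for s in ss.spawn(4)]

    cell_ids = [f"CL_A_{i + 1:02d}" for i in range(config.n_cell_a)] + [
        f"CL_B_{i + 1:02d}" for i in range(config.n_cell_b)
    ]
    cell_labels = ["A"] * config.n_cell_a + ["B"] * config.n_cell_b
    patient_ids = [f"PT_{i + 1:03d}" for i in range(config.n_patients)]

    # latent patient labels: unassignable first (fixed count), then B among the rest
    n_unassign = int(round(config.frac_unassignable * config.n_patients))
    n_assignable = config.n_patients - n_unassign
    n_pat_b = int(round(config.frac_patient_b * n_assignable))
    pat_labels = np.array(["A"] * (n_assignable - n_pat_b) + ["B"] * n_pat_b + ["unassignable"] * n_unassign)
    rng_psi.shuffle(pat_labels)

    events = _event_frame(config.n_events)
    # informative events are a fixed, evenly spaced subset: cohorts drawn
    # with different seeds share the same planted biology, so hold-out
    # cohorts are valid validation sets for a recovered signature
    inf_idx = np.arange(config.n_informative) * config.n_events // config.n_informative
    informative = sorted(events.index[inf_idx])
    informative_mask = events.index.isin(informative)

    lo, hi = config.purity_range
    purity = np.where(
        pat_labels == "unassignable",
        rng_psi.uniform(0.0, 0.2 * hi, size=config.n_patients),
        rng_psi.uniform(lo, hi, size=config.n_patients),
    )

    # hidden subtype used for PSI mixing of unassignable tumours: coin flip
    hidden = np.where(
        pat_labels == "unassignable",
        np.where(rng_psi.random(config.n_patients) < config.frac_patient_b, "B", "A"),
        pat_labels,
    )

    def latent_matrix(sample_labels: np.ndarray) -> np.ndarray:
        """(events x samples) latent PSI draws for pure samples."""
        n = len(sample_labels)
        out = np.empty((config.n_events, n))
        for j, lab in enumerate(sample_labels):
            means = np.where(
                informative_mask,
                config.psi_a if lab == "A" else config.psi_b,
                config.psi_background,
            )
            a = np.clip(means, 1e-6, 1 - 1e-6) * config.concentration
            b = (1 - np.clip(means, 1e-6, 1 - 1e-6)) * config.concentration
            out[:, j] = rng_psi.beta(a, b)
        return out

    psi_cells = latent_matrix(np.array(cell_labels))
    psi_pat_pure = latent_matrix(hidden)
    psi_patients = purity[None, :] * psi_pat_pure + (1.0 - purity[None, :]) * config.psi_background

    def sample_counts(latent: np.ndarray, sample_ids: list[str]) -> EventCountTable:
        depth = rng_counts.poisson(config.depth_mean, size=latent.shape)
        ic = rng_counts.binomial(depth, np.clip(latent, 0.0, 1.0))
        sc = depth - ic
        return EventCountTable(
            events.copy(),
            pd.DataFrame(ic.astype(np.int64), index=events.index, columns=sample_ids),
            pd.DataFrame(sc.astype(np.int64), index=events.index, columns=sample_ids),
        )

    cells = sample_counts(psi_cells, cell_ids)
    patients = sample_counts(psi_patients, patient_ids)

    # expression: log2 TPM ~ N(mu_g + effect, 0.5); planted +/- log2fc on DE genes in subtype B
    gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    de_idx = np.arange(config.n_de_genes) * config.n_genes // max(config.n_de_genes, 1)
    de_genes = sorted(pd.Index(gene_ids)[de_idx])
    de_mask = pd.Index(gene_ids).isin(de_genes)
    base_mu = rng_expr.uniform(2.0, 9.0, size=config.n_genes)
    de_sign = np.where(np.arange(config.n_genes) % 2 == 0, 1.0, -1.0)
    effect = np.where(de_mask, de_sign * config.log2fc_effect, 0.0)

    all_ids = cell_ids + patient_ids
    is_b = np.array([lab == "B" for lab in cell_labels] + [h == "B" for h in hidden], dtype=float)
    # patients' effect attenuated by purity; cells are pure
    pur_all = np.concatenate([np.ones(len(cell_ids)), purity])
    log2tpm = (
        base_mu[:, None]
        + effect[:, None] * (is_b * pur_all)[None, :]
        + rng_expr.normal(0.0, 0.5, size=(config.n_genes, len(all_ids)))
    )
    expression = pd.DataFrame(2.0 ** log2tpm, index=pd.Index(gene_ids, name="gene_id"), columns=all_ids)

    # survival: exponential event times; unassignable tumours at baseline hazard
    hazard = np.where(pat_labels == "B", config.baseline_hazard * config.hazard_ratio_true, config.baseline_hazard)
    t_event = rng_surv.exponential(1.0 / hazard)
    t_censor = rng_surv.uniform(0.0, config.censor_horizon, size=config.n_patients)
    time = np.minimum(t_event, t_censor)
    observed = (t_event <= t_censor).astype(int)
    survival = pd.DataFrame(
        {"time": time, "event": observed, "endpoint": "DSS"},
        index=pd.Index(patient_ids, name="sample_id"),
    )

    annotation = pd.DataFrame(
        {
            "domain": ["cell_line"] * len(cell_ids) + ["patient"] * len(patient_ids),
            "subtype": cell_labels + [""] * len(patient_ids),
        },
        index=pd.Index(all_ids, name="sample_id"),
    )

    truth = SyntheticTruth(
        labels=pd.Series(
            cell_labels + pat_labels.tolist(), index=pd.Index(all_ids, name="sample_id"), name="label"
        ),
        informative_event_ids=informative,
        de_gene_ids=de_genes,
        purity=pd.Series(purity, index=pd.Index(patient_ids, name="sample_id"), name="purity"),
        true_hazard_ratio=config.hazard_ratio_true,
    )
    return Cohort(cells, patients, expression, annotation, survival, truth)


# ---------------------------------------------------------------- fixtures

def write_fixture(cohort: Cohort, directory: str | Path) -> None:
    """Write all cohort tables as TSV (+ truth JSON) into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.cells.to_tsv(d / "cell_counts.tsv")
    cohort.patients.to_tsv(d / "patient_counts.tsv")
    cohort.expression.to_csv(d / "expression.tsv", sep="\t")
    cohort.annotation.to_csv(d / "annotation.tsv", sep="\t")
    cohort.survival.to_csv(d / "survival.tsv", sep="\t")
    truth = {
        "labels": cohort.truth.labels.to_dict(),
        "informative_event_ids": cohort.truth.informative_event_ids,
        "de_gene_ids": cohort.truth.de_gene_ids,
        "purity": cohort.truth.purity.to_dict(),
        "true_hazard_ratio": cohort.truth.true_hazard_ratio,
    }
    (d / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_fixture(directory: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_fixture` (round-trip identity)."""
    d = Path(directory)
    cells = EventCountTable.from_tsv(d / "cell_counts.tsv")
    patients = EventCountTable.from_tsv(d / "patient_counts.tsv")
    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col="gene_id", float_precision="round_trip")
    annotation = pd.read_csv(d / "annotation.tsv", sep="\t", index_col="sample_id", keep_default_na=False)
    survival = pd.read_csv(d / "survival.tsv", sep="\t", index_col="sample_id", float_precision="round_trip")
    raw = json.loads((d / "truth.json").read_text())
    labels = pd.Series(raw["labels"], name="label")
    labels.index.name = "sample_id"
    labels = labels.loc[annotation.index]
    purity = pd.Series(raw["purity"], name="purity")
    purity.index.name = "sample_id"
    purity = purity.loc[patients.samples]
    truth = SyntheticTruth(
        labels=labels,
        informative_event_ids=list(raw["informative_event_ids"]),
        de_gene_ids=list(raw["de_gene_ids"]),
        purity=purity,
        true_hazard_ratio=float(raw["true_hazard_ratio"]),
    )
    return Cohort(cells, patients, expression, annotation, survival, truth)
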