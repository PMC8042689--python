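"""Cassette-exon inclusion/skipping counts, PSI, and event-level screens.

The quantitative substrate of the whole pipeline is the per-event,
per-sample pair of junction read counts: inclusion counts (IC, reads
supporting exon inclusion) and skipping counts (SC, reads supporting the
exon being skipped).  Percentage spliced-in is the simple ratio

    PSI = IC / (IC + SC)

undefined (missing) when no junction read covers the event in a sample.
Differential splicing between two sample groups is summarised by
deltaPSI = mean PSI(B) - mean PSI(A) together with a directional
posterior probability estimated from per-sample Beta(IC+1, SC+1)
posteriors; an event is called reliable when |deltaPSI| exceeds 0.1 and
the probability reaches 0.95 (both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventCountTable",
    "compute_psi",
    "filter_events",
    "delta_psi",
    "export_signature_bed",
    "DELTA_PSI_THRESHOLD",
    "PROBABILITY_THRESHOLD",
]

#: default reliability thresholds for a differential event
DELTA_PSI_THRESHOLD = 0.1
PROBABILITY_THRESHOLD = 0.95

EVENT_COLUMNS = ["gene", "chrom", "start", "end", "strand"]


class SchemaError(ValueError):
    """Raised when an on-disk table does not match the expected layout."""


@dataclass
class EventCountTable:
    """Per-event, per-sample IC/SC counts with genomic coordinates.

    Parameters
    ----------
    events : DataFrame indexed by unique ``event_id`` with columns
        ``gene, chrom, start, end, strand`` (1-based inclusive interval,
        strand one of ``+ - .``).
    ic, sc : DataFrames (events x samples) of non-negative integers,
        sharing the event index and an identical sample set.
    """

    events: pd.DataFrame
    ic: pd.DataFrame
    sc: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.events.index.is_unique:
            raise SchemaError("event ids must be unique")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise SchemaError(f"event table lacks columns {missing}")
        if not (self.ic.index.equals(self.events.index) and self.sc.index.equals(self.events.index)):
            raise SchemaError("ic/sc indices must match the event table")
        if list(self.ic.columns) != list(self.sc.columns):
            raise SchemaError("ic and sc must cover the same samples")
        if (self.ic.to_numpy() < 0).any() or (self.sc.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def samples(self) -> list[str]:
        return list(self.ic.columns)

    @property
    def event_ids(self) -> list[str]:
        return list(self.events.index)

    def psi(self) -> pd.DataFrame:
        """Events x samples PSI matrix; NaN where IC+SC = 0."""
        ic = self.ic.to_numpy(dtype=float)
        total = ic + self.sc.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(total > 0, ic / np.where(total > 0, total, 1.0), np.nan)
        return pd.DataFrame(psi, index=self.ic.index, columns=self.ic.columns)

    def subset_samples(self, samples: Sequence[str]) -> "EventCountTable":
        unknown = [s for s in samples if s not in self.ic.columns]
        if unknown:
            raise KeyError(f"unknown samples: {unknown}")
        return EventCountTable(self.events.copy(), self.ic[list(samples)].copy(), self.sc[list(samples)].copy())

    def subset_events(self, event_ids: Sequence[str]) -> "EventCountTable":
        idx = pd.Index(event_ids)
        return EventCountTable(self.events.loc[idx].copy(), self.ic.loc[idx].copy(), self.sc.loc[idx].copy())

    def equals(self, other: "EventCountTable") -> bool:
        return (
            self.events.equals(other.events)
            and self.ic.equals(other.ic)
            and self.sc.equals(other.sc)
        )

    # --- TSV round trip: wide layout, one <sample>.IC / <sample>.SC pair per sample ---

    def to_tsv(self, path: str | Path) -> None:
        wide = self.events.copy()
        for s in self.samples:
            wide[f"{s}.IC"] = self.ic[s]
            wide[f"{s}.SC"] = self.sc[s]
        wide.to_csv(path, sep="\t", index_label="event_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventCountTable":
        wide = pd.read_csv(path, sep="\t", index_col="event_id")
        ic_cols = [c for c in wide.columns if c.endswith(".IC")]
        sc_cols = [c for c in wide.columns if c.endswith(".SC")]
        ic_samples = [c[:-3] for c in ic_cols]
        sc_samples = [c[:-3] for c in sc_cols]
        for s in sc_samples:
            if s not in ic_samples:
                raise SchemaError(f"sample '{s}' has an SC column but no IC column")
        for s in ic_samples:
            if s not in sc_samples:
                raise SchemaError(f"sample '{s}' has an IC column but no SC column")
        events = wide[EVENT_COLUMNS].copy()
        ic = wide[[f"{s}.IC" for s in ic_samples]].astype(np.int64)
        ic.columns = ic_samples
        sc = wide[[f"{s}.SC" for s in ic_samples]].astype(np.int64)
        sc.columns = ic_samples
        return cls(events, ic, sc)


def compute_psi(ic, sc):
    """PSI = ic/(ic+sc); NaN when there is no read evidence.

    Accepts scalars or array-likes; raises on negative counts.
    """
    ic = np.asarray(ic, dtype=float)
    sc = np.asarray(sc, dtype=float)
    if (ic < 0).any() or (sc < 0).any():
        raise ValueError("negative read counts")
    total = ic + sc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, ic / np.where(total > 0, total, 1.0), np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def filter_events(
    table: EventCountTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_total: int = 10,
    per_sample: bool = False,
) -> pd.Series:
    """Coverage reliability filter: IC+SC >= ``min_total`` in both groups.

    By default the counts are pooled within each group before comparison
    (replicate-pooled reading); ``per_sample=True`` instead requires the
    threshold in every individual sample.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    for s in group_a + group_b:
        if s not in table.ic.columns:
            raise KeyError(f"unknown sample in group spec: '{s}'")
    total = table.ic + table.sc
    if per_sample:
        ok_a = (total[group_a] >= min_total).all(axis=1)
        ok_b = (total[group_b] >= min_total).all(axis=1)
    else:
        ok_a = total[group_a].sum(axis=1) >= min_total
        ok_b = total[group_b].sum(axis=1) >= min_total
    out = ok_a & ok_b
    out.name = "pass"
    return out


def delta_psi(
    table: EventCountTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_draws: int = 10_000,
    seed: int | None = None,
    delta_threshold: float = DELTA_PSI_THRESHOLD,
    prob_threshold: float = PROBABILITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-event deltaPSI (mean B - mean A) with a directional posterior probability.

    For each sample the event-level PSI posterior is Beta(IC+1, SC+1)
    (uniform prior).  ``n_draws`` joint draws are averaged within each
    group (over samples with read evidence) and the probability reported
    is max(Pr(delta > 0), Pr(delta < 0)) — the posterior confidence that
    the sign of the splicing change is as estimated.

    Returns a DataFrame with columns ``delta_psi, probability,
    significant, missing`` indexed by event id.  Events where one group
    has no read evidence at all are flagged missing (NaN delta).
    """
    group_a, group_b = list(group_a), list(group_b)
    for s in group_a + group_b:
        if s not in table.ic.columns:
            raise KeyError(f"unknown sample in group spec: '{s}'")
    rng = np.random.default_rng(seed)
    psi = table.psi()
    mean_a = psi[group_a].mean(axis=1, skipna=True)
    mean_b = psi[group_b].mean(axis=1, skipna=True)
    delta = mean_b - mean_a

    prob = np.full(len(table.events), np.nan)
    missing = delta.isna().to_numpy()
    ic = table.ic
    sc = table.sc
    for i, ev in enumerate(table.events.index):
        if missing[i]:
            continue
        draws_mean = []
        for grp in (group_a, group_b):
            a = ic.loc[ev, grp].to_numpy(dtype=float)
            b = sc.loc[ev, grp].to_numpy(dtype=float)
            covered = (a + b) > 0
            # (draws x covered-samples) Beta posterior draws, averaged per draw
            g = rng.beta(a[covered] + 1.0, b[covered] + 1.0, size=(n_draws, int(covered.sum())))
            draws_mean.append(g.mean(axis=1))
        d = draws_mean[1] - draws_mean[0]
        p_pos = float(np.mean(d > 0))
        prob[i] = max(p_pos, 1.0 - p_pos)

    out = pd.DataFrame(
        {
            "delta_psi": delta,
            "probability": prob,
            "missing": missing,
        },
        index=table.events.index,
    )
    out["significant"] = (
        (out["delta_psi"].abs() > delta_threshold)
        & (out["probability"] >= prob_threshold)
        & ~out["missing"]
    )
    return out


def export_signature_bed(signature: pd.DataFrame, path: str | Path) -> None:
    """Write a signature table as BED6.

    Expects columns ``gene, chrom, start, end, strand, delta_psi`` with
    1-based inclusive coordinates; writes 0-based half-open intervals,
    name ``gene:event_id`` and score = round(1000*|delta_psi|) clipped
    to [0, 1000].
    """
    required = ["gene", "chrom", "start", "end", "strand", "delta_psi"]
    missing = [c for c in required if c not in signature.columns]
    if missing:
        raise ValueError(f"signature table lacks columns {missing}")
    if signature[["chrom", "start", "end"]].isna().any().any():
        raise ValueError("missing coordinates in signature table")
    with open(path, "w") as fh:
        for ev, row in signature.iterrows():
            score = int(round(1000 * abs(float(row["delta_psi"]))))
            score = min(max(score, 0), 1000)
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                f"{row['gene']}:{ev}\t{score}\t{row['strand']}\n"
            )


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file back into 1-based inclusive intervals."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start0", "end", "name", "score", "strand"],
    )
    gene_event = bed["name"].str.split(":", n=1, expand=True)
    out = pd.DataFrame(
        {
            "gene": gene_event[0],
            "chrom": bed["chrom"],
            "start": bed["start0"] + 1,
            "end": bed["end"],
            "strand": bed["strand"],
            "score": bed["score"],
        }
    )
    out.index = pd.Index(gene_event[1], name="event_id")
    return out
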