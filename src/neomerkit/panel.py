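"""Cancer-type neomer panels: recurrence filtering and summary statistics.

A panel aggregates per-mutation neomer records across patients: each k-mer
keeps its distinct-patient recurrence, the multisets of cancer types / organs
/ variant classes it was seen with, and (after annotation) its per-population
not-from-germline confidence.  Panels are compared with the Jaccard index and
summarized as shared-by-exactly-N-patients histograms.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .germline import POPULATIONS, GermlineNullomerRecord
from .provenance import read_tsv_with_header, write_tsv_with_header
from .somatic import NeomerRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_RECURRENCE = 2
DEFAULT_MIN_CONFIDENCE = 0.95

_VALID_POPULATIONS = ("overall", *POPULATIONS)


@dataclass
class PanelEntry:
    n_patients: int
    cancer_types: Counter = field(default_factory=Counter)
    organs: Counter = field(default_factory=Counter)
    variant_classes: Counter = field(default_factory=Counter)
    # population -> probability the k-mer is not of germline origin; 1.0 when
    # the k-mer never appears in the germline records
    p_not_germline: dict[str, float] = field(default_factory=dict)

    def confidence(self, population: str) -> float:
        return self.p_not_germline.get(population, 1.0)


@dataclass
class NeomerPanel:
    k: int
    filters_applied: dict
    entries: dict[str, PanelEntry]

    @property
    def kmers(self) -> set[str]:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def build_panel(
    records: list[NeomerRecord],
    min_recurrence: int = DEFAULT_MIN_RECURRENCE,
    cancer_type: str | None = None,
    organ: str | None = None,
    stage: str | None = None,
) -> NeomerPanel:
    """Group records by k-mer and keep those seen in >= min_recurrence patients.

    Recurrence counts distinct sample_ids: the same k-mer produced twice in one
    patient (by different mutations) counts once.
    """
    if min_recurrence < 1:
        raise ParameterError("min_recurrence must be >= 1")
    ks = {r.k for r in records}
    if len(ks) > 1:
        raise ParameterError(f"records mix k values: {sorted(ks)}")
    k = ks.pop() if ks else 0
    selected = [
        r
        for r in records
        if (cancer_type is None or r.cancer_type == cancer_type)
        and (organ is None or r.organ == organ)
        and (stage is None or r.stage == stage)
    ]
    patients: dict[str, set[str]] = {}
    meta: dict[str, PanelEntry] = {}
    for r in selected:
        entry = meta.setdefault(r.kmer, PanelEntry(n_patients=0))
        pats = patients.setdefault(r.kmer, set())
        if r.sample_id not in pats:
            pats.add(r.sample_id)
            # multisets count per-patient provenance, not per-record
            if r.cancer_type:
                entry.cancer_types[r.cancer_type] += 1
            if r.organ:
                entry.organs[r.organ] += 1
        if r.variant_class:
            entry.variant_classes[r.variant_class] += 1
    entries = {
        kmer: PanelEntry(
            n_patients=len(patients[kmer]),
            cancer_types=meta[kmer].cancer_types,
            organs=meta[kmer].organs,
            variant_classes=meta[kmer].variant_classes,
        )
        for kmer in sorted(patients)
        if len(patients[kmer]) >= min_recurrence
    }
    filters = {
        "min_recurrence": min_recurrence,
        "cancer_type": cancer_type,
        "organ": organ,
        "stage": stage,
    }
    return NeomerPanel(k=k, filters_applied=filters, entries=entries)


def annotate_germline(
    panel: NeomerPanel, germline_records: list[GermlineNullomerRecord]
) -> NeomerPanel:
    """Attach per-population confidences to panel entries (in place)."""
    by_kmer = {r.kmer: r for r in germline_records}
    for kmer, entry in panel.entries.items():
        rec = by_kmer.get(kmer)
        if rec is None:
            continue
        entry.p_not_germline = {
            "overall": rec.p_not_germline_overall,
            **rec.p_not_germline_by_pop,
        }
    return panel


def apply_confidence_filter(
    panel: NeomerPanel,
    germline_records: list[GermlineNullomerRecord],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    population: str = "overall",
) -> NeomerPanel:
    """Drop entries whose not-from-germline confidence is below the threshold.

    k-mers absent from the germline records have confidence 1.0 (no common
    variant can create them) and always survive.
    """
    if population not in _VALID_POPULATIONS:
        raise ParameterError(
            f"unknown population {population!r}; valid: {', '.join(_VALID_POPULATIONS)}"
        )
    annotate_germline(panel, germline_records)
    kept = {
        kmer: entry
        for kmer, entry in panel.entries.items()
        if entry.confidence(population) >= min_confidence
    }
    filters = dict(panel.filters_applied)
    filters.update({"min_confidence": min_confidence, "population": population})
    return NeomerPanel(k=panel.k, filters_applied=filters, entries=kept)


@dataclass
class JaccardMatrix:
    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def jaccard_matrix(panels: dict[str, NeomerPanel]) -> JaccardMatrix:
    """Pairwise |Ki n Kj| / |Ki u Kj| over panel k-mer sets.

    Two empty panels have Jaccard 0 by convention (keeps the matrix total);
    a non-empty panel against itself is 1.
    """
    ks = {p.k for p in panels.values() if len(p)}
    if len(ks) > 1:
        raise ParameterError(f"panels mix k values: {sorted(ks)}")
    labels = list(panels)
    sets = [panels[name].kmers for name in labels]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            union = len(sets[i] | sets[j])
            val = len(sets[i] & sets[j]) / union if union else 0.0
            values[i, j] = values[j, i] = val
    return JaccardMatrix(labels, values)


@dataclass
class PatientSummary:
    per_patient: pd.DataFrame  # sample_id, cancer_type, organ, n_distinct_neomers
    shared_by_histogram: dict[int, int]  # N patients -> number of k-mers
    median_by_group: pd.DataFrame  # (organ, cancer_type) -> median count


def patient_summaries(records: list[NeomerRecord]) -> PatientSummary:
    """Distinct neomers per patient and the shared-by-exactly-N histogram."""
    ks = {r.k for r in records}
    if len(ks) > 1:
        raise ParameterError(f"records mix k values: {sorted(ks)}")
    if not records:
        empty = pd.DataFrame(
            columns=["sample_id", "cancer_type", "organ", "n_distinct_neomers"]
        )
        return PatientSummary(empty, {}, pd.DataFrame(columns=["organ", "cancer_type", "median_neomers"]))
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "cancer_type": [r.cancer_type or "" for r in records],
            "organ": [r.organ or "" for r in records],
            "kmer": [r.kmer for r in records],
        }
    )
    per_patient = (
        df.groupby("sample_id")
        .agg(
            cancer_type=("cancer_type", "first"),
            organ=("organ", "first"),
            n_distinct_neomers=("kmer", "nunique"),
        )
        .reset_index()
    )
    patients_per_kmer = df.groupby("kmer")["sample_id"].nunique()
    histogram = dict(Counter(int(n) for n in patients_per_kmer))
    medians = (
        per_patient.groupby(["organ", "cancer_type"])["n_distinct_neomers"]
        .median()
        .rename("median_neomers")
        .reset_index()
    )
    return PatientSummary(per_patient, histogram, medians)


def _counter_str(c: Counter) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(c.items()))


def _parse_counter(s: str) -> Counter:
    c: Counter = Counter()
    for part in (s or "").split(";"):
        if part:
            name, _, count = part.rpartition(":")
            c[name] = int(count)
    return c


def write_panel(panel: NeomerPanel, path: str | Path, provenance: dict | None = None) -> None:
    rows = []
    for kmer, e in panel.entries.items():
        row = {
            "kmer": kmer,
            "n_patients": e.n_patients,
            "cancer_types": _counter_str(e.cancer_types),
            "organs": _counter_str(e.organs),
            "variant_classes": _counter_str(e.variant_classes),
            "p_not_germline_overall": repr(e.confidence("overall")),
        }
        for pop in POPULATIONS:
            row[f"p_not_germline_{pop}"] = repr(e.confidence(pop))
        rows.append(row)
    cols = [
        "kmer",
        "n_patients",
        "cancer_types",
        "organs",
        "variant_classes",
        "p_not_germline_overall",
    ] + [f"p_not_germline_{p}" for p in POPULATIONS]
    meta = {
        "k": panel.k,
        "filters": json.dumps(panel.filters_applied, sort_keys=True),
    }
    meta.update(provenance or {})
    write_tsv_with_header(pd.DataFrame(rows, columns=cols), path, meta)


def read_panel(path: str | Path) -> NeomerPanel:
    df, meta = read_tsv_with_header(path, dtype=str)
    entries = {}
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        probs = {"overall": float(rec["p_not_germline_overall"])}
        for pop in POPULATIONS:
            probs[pop] = float(rec[f"p_not_germline_{pop}"])
        entries[rec["kmer"]] = PanelEntry(
            n_patients=int(rec["n_patients"]),
            cancer_types=_parse_counter(rec["cancer_types"]),
            organs=_parse_counter(rec["organs"]),
            variant_classes=_parse_counter(rec["variant_classes"]),
            p_not_germline=probs,
        )
    filters = json.loads(meta.get("filters", "{}"))
    return NeomerPanel(k=int(meta["k"]), filters_applied=filters, entries=entries)
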