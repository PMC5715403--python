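"""Database curation and per-taxon architecture frequencies.

``curate`` applies the six-motif fingerprint to a candidate database and
reports how many sequences survive; ``reclassify_rejected`` asks how many of
the removed sequences carry a NifX-like domain (most false NifB annotations
are in fact NifX proteins, which share the C-terminal fold but lack the
AdoMet cysteine triad).  ``architecture_frequencies`` tabulates architecture
counts and within-row percentages per (superkingdom, group).

The reduction fraction is reported to three decimals as computed from the
data, never coerced to a published headline figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .architecture import (
    NIFX_LIKE,
    NOT_NIFB,
    SINGLE,
    THREE_DOMAIN,
    TWO_DOMAIN,
    ArchitectureCall,
    ReferencePanel,
    detect_homology_domain,
)
from .core_io import ProteinRecord, TaxonomyRecord
from .motifs import Fingerprint, FingerprintResult, match_fingerprint

ARCH_COLUMNS = (SINGLE, TWO_DOMAIN, THREE_DOMAIN)
UNASSIGNED = ("unassigned", "unassigned")


@dataclass
class CurationReport:
    """Outcome of the fingerprint filter over a candidate database."""

    n_input: int
    n_retained: int
    n_removed: int
    reduction_fraction: float
    per_record: list[FingerprintResult]
    retained: list[ProteinRecord]
    removed: list[ProteinRecord]
    removed_reclassified: Optional[int] = None


def curate(records: Sequence[ProteinRecord],
           fingerprint: Fingerprint) -> CurationReport:
    """Score every record against the fingerprint and split the database."""
    if not records:
        raise ValueError("empty dataset")
    per_record = [match_fingerprint(r, fingerprint) for r in records]
    retained = [r for r, res in zip(records, per_record) if res.passed]
    removed = [r for r, res in zip(records, per_record) if not res.passed]
    n = len(records)
    return CurationReport(
        n_input=n,
        n_retained=len(retained),
        n_removed=len(removed),
        reduction_fraction=round(len(removed) / n, 3),
        per_record=per_record,
        retained=retained,
        removed=removed,
    )


def reclassify_rejected(report: CurationReport, panel: ReferencePanel) -> int:
    """Count removed records in which a NifX-like domain is detectable.

    Scans each removed record's full length; the count is also stored on the
    report (``removed_reclassified``).
    """
    count = 0
    for rec in report.removed:
        hit = detect_homology_domain(rec, panel, NIFX_LIKE)
        if hit is not None:
            count += 1
    report.removed_reclassified = count
    return count


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class FrequencyTable:
    """Architecture counts and within-row percentages per taxon group."""

    counts: pd.DataFrame       # index (superkingdom, group), columns ARCH_COLUMNS
    percentages: pd.DataFrame  # same shape, integer percent (round half up)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Combined counts + percentages table for reporting."""
        out = self.counts.copy()
        for col in ARCH_COLUMNS:
            out[f"{col}_pct"] = self.percentages[col]
        out["total"] = self.row_totals
        return out


def architecture_frequencies(
    calls: Iterable[ArchitectureCall],
    taxonomy_map: Mapping[str, TaxonomyRecord],
) -> FrequencyTable:
    """Tabulate architecture frequencies per (superkingdom, group).

    NOT_NIFB calls are excluded; calls without a taxonomy entry are counted
    under an ``(unassigned, unassigned)`` row rather than dropped.
    """
    tallies: dict[tuple[str, str], dict[str, int]] = {}
    for call in calls:
        if call.label == NOT_NIFB:
            continue
        tax = taxonomy_map.get(call.record_id)
        key = (tax.superkingdom, tax.group) if tax is not None else UNASSIGNED
        row = tallies.setdefault(key, {c: 0 for c in ARCH_COLUMNS})
        row[call.label] += 1

    index = pd.MultiIndex.from_tuples(
        sorted(tallies), names=["superkingdom", "group"]
    )
    counts = pd.DataFrame(
        [[tallies[key][c] for c in ARCH_COLUMNS] for key in sorted(tallies)],
        index=index, columns=list(ARCH_COLUMNS), dtype=int,
    )
    pct = counts.copy()
    for key in counts.index:
        total = counts.loc[key].sum()
        for c in ARCH_COLUMNS:
            pct.loc[key, c] = (
                _round_half_up(100.0 * counts.loc[key, c] / total) if total else 0
            )
    return FrequencyTable(counts=counts, percentages=pct)


def report_to_frame(report: CurationReport) -> pd.DataFrame:
    """Per-record curation table (passed flag plus missing motifs)."""
    return pd.DataFrame(
        {
            "record_id": [res.record_id for res in report.per_record],
            "passed": [res.passed for res in report.per_record],
            "missing_motifs": [",".join(res.missing) for res in report.per_record],
        }
    )
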