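"""Ground-truth synthetic NifB datasets.

The generator emits protein families with the statistical structure the
pipeline assumes: every NifB-class sequence carries the six SAM-radical
motifs in order with random spacers, two- and three-domain records
additionally carry NifX-like / NifN-like segments copied from shipped
templates and mutated to a configurable identity, and a configurable
fraction of records are NifX-only contaminants guaranteed (by rejection
sampling) to fail the fingerprint.  Global substitution noise, when enabled,
never touches motif literal positions so the planted truth labels stay exact.

Default group mix mirrors the observed distribution of architectures across
diazotroph lineages: an archaeal group that is 100% single-domain, bacterial
groups dominated by the two-domain form (~70-80%), and a Firmicutes-like
group carrying all three architectures (55 / 32.5 / 12.5%).  Proportions are
converted to integer counts by largest-remainder rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .architecture import NIFN_LIKE, NIFX_LIKE, SAM_RADICAL, SINGLE, \
    THREE_DOMAIN, TWO_DOMAIN, default_panel
from .core_io import AMINO_ACIDS, ProteinRecord, TaxonomyRecord, write_fasta
from .motifs import Fingerprint, LITERAL, default_fingerprint, match_fingerprint

CONTAMINANT = "CONTAMINANT"
NIFB_LABELS = (SINGLE, TWO_DOMAIN, THREE_DOMAIN)


@dataclass(frozen=True)
class GroupSpec:
    """One taxon group: size and architecture proportions."""

    superkingdom: str
    group: str
    n_records: int
    proportions: tuple[float, float, float]  # SINGLE, TWO_DOMAIN, THREE_DOMAIN

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"invalid proportions for {self.group!r}: must sum to 1"
            )


DEFAULT_GROUPS = (
    GroupSpec("Bacteria", "Firmicutes", 50, (0.55, 0.325, 0.125)),
    GroupSpec("Bacteria", "Gammaproteobacteria", 50, (0.25, 0.70, 0.05)),
    GroupSpec("Bacteria", "Cyanobacteria", 50, (0.20, 0.80, 0.0)),
    GroupSpec("Archaea", "Euryarchaeota", 50, (1.0, 0.0, 0.0)),
)


@dataclass
class SyntheticConfig:
    """Generator parameters.  Defaults are the standard study conditions."""

    seed: int = 0
    groups: Sequence[GroupSpec] = DEFAULT_GROUPS
    contaminant_fraction: float = 0.2
    substitution_rate: float = 0.0
    spacer_length_range: tuple[int, int] = (8, 16)
    domain_identity: float = 0.7
    ablate_motif: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.contaminant_fraction < 1.0):
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if not (0.0 <= self.substitution_rate < 0.3):
            raise ValueError("substitution_rate must be in [0, 0.3)")
        lo, hi = self.spacer_length_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid spacer_length_range")
        if not (0.3 < self.domain_identity <= 1.0):
            raise ValueError("domain_identity must be in (0.3, 1]")


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one generated record."""

    record_id: str
    superkingdom: str
    group: str
    label: str  # SINGLE / TWO_DOMAIN / THREE_DOMAIN / CONTAMINANT
    motif_starts: tuple[int, ...]
    domains: tuple[tuple[str, int, int], ...]  # (kind, start, end)


@dataclass
class SyntheticDataset:
    records: list[ProteinRecord]
    taxonomy: list[TaxonomyRecord]
    truth: list[TruthEntry]

    def truth_by_id(self) -> dict[str, TruthEntry]:
        return {t.record_id: t for t in self.truth}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "dataset.fasta"
        tax = out / "taxonomy.tsv"
        truth = out / "truth.tsv"
        write_fasta(self.records, fasta)
        with open(tax, "w") as fh:
            fh.write("record_id\tsuperkingdom\tgroup\n")
            for t in self.taxonomy:
                fh.write(f"{t.record_id}\t{t.superkingdom}\t{t.group}\n")
        with open(truth, "w") as fh:
            fh.write("record_id\tsuperkingdom\tgroup\tlabel\tmotif_starts\tdomains\n")
            for t in self.truth:
                starts = ",".join(str(s) for s in t.motif_starts)
                doms = ";".join(f"{k}:{s}-{e}" for k, s, e in t.domains)
                fh.write(f"{t.record_id}\t{t.superkingdom}\t{t.group}\t"
                         f"{t.label}\t{starts}\t{doms}\n")
        return {"fasta": fasta, "taxonomy": tax, "truth": truth}


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Convert proportions to integer counts summing to ``n``."""
    raw = [n * p for p in proportions]
    counts = [int(x) for x in raw]
    remainders = [x - c for x, c in zip(raw, counts)]
    short = n - sum(counts)
    # ties broken toward the earlier class: stable sort on -remainder
    order = sorted(range(len(proportions)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


def _spacer(rng: np.random.Generator, config: SyntheticConfig) -> str:
    lo, hi = config.spacer_length_range
    return _random_residues(rng, int(rng.integers(lo, hi + 1)))


def _motif_instance(rng: np.random.Generator, pattern) -> tuple[str, list[int]]:
    """Render a pattern to residues; return (instance, literal offsets)."""
    parts: list[str] = []
    literal_offsets: list[int] = []
    pos = 0
    for tok in pattern.tokens:
        if tok.kind == LITERAL:
            parts.append(tok.value)
            literal_offsets.append(pos)
            pos += 1
        else:
            parts.append(_random_residues(rng, tok.count))
            pos += tok.count
    return "".join(parts), literal_offsets


def _mutated_copy(rng: np.random.Generator, template: str,
                  identity: float) -> str:
    """Substitute residues so the copy keeps ``identity`` to the template."""
    seq = list(template)
    n_mut = int(round(len(seq) * (1.0 - identity)))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for p in positions:
        others = AMINO_ACIDS.replace(seq[p], "")
        seq[p] = others[int(rng.integers(0, len(others)))]
    return "".join(seq)


def _apply_noise(rng: np.random.Generator, sequence: str,
                 protected: set[int], rate: float) -> str:
    if rate <= 0:
        return sequence
    seq = list(sequence)
    hits = rng.random(len(seq)) < rate
    for p in np.nonzero(hits)[0]:
        if int(p) in protected:
            continue
        others = AMINO_ACIDS.replace(seq[p], "")
        seq[p] = others[int(rng.integers(0, len(others)))]
    return "".join(seq)


def _templates():
    panel = default_panel()
    return panel.nifx[0].sequence, panel.nifn[0].sequence


def generate_nifb_record(
    config: SyntheticConfig,
    label: str,
    rng: np.random.Generator,
    record_id: str = "syn",
    fingerprint: Optional[Fingerprint] = None,
    ablate_motif: Optional[str] = None,
) -> tuple[ProteinRecord, TruthEntry]:
    """One NifB-class record with its ground truth.

    ``ablate_motif`` replaces the named motif with random residues (rejection
    sampled so the fingerprint fails), producing a NifB-like decoy.
    """
    if label not in NIFB_LABELS:
        raise ValueError(f"unknown NifB label {label!r}")
    fp = fingerprint or default_fingerprint()
    nifx_tpl, nifn_tpl = _templates()
    ablate = ablate_motif if ablate_motif is not None else config.ablate_motif

    for _ in range(100):  # rejection loop only matters when ablating
        parts: list[str] = []
        pos = 0  # 0-based running offset
        domains: list[tuple[str, int, int]] = []
        motif_starts: list[int] = []
        protected: set[int] = set()

        if label == THREE_DOMAIN:
            seg = _mutated_copy(rng, nifn_tpl, config.domain_identity)
            domains.append((NIFN_LIKE, pos + 1, pos + len(seg)))
            parts.append(seg)
            pos += len(seg)

        lead = _spacer(rng, config)
        parts.append(lead)
        pos += len(lead)

        sam_start = pos + 1
        for k, pattern in enumerate(fp.patterns):
            if k:
                sp = _spacer(rng, config)
                parts.append(sp)
                pos += len(sp)
            if ablate is not None and pattern.name == ablate:
                instance = _random_residues(rng, pattern.span)
                offsets: list[int] = []
            else:
                instance, offsets = _motif_instance(rng, pattern)
            motif_starts.append(pos + 1)
            protected.update(pos + o for o in offsets)
            parts.append(instance)
            pos += len(instance)
        sam_end = pos
        domains.append((SAM_RADICAL, sam_start, sam_end))

        tail = _spacer(rng, config)
        parts.append(tail)
        pos += len(tail)

        if label in (TWO_DOMAIN, THREE_DOMAIN):
            seg = _mutated_copy(rng, nifx_tpl, config.domain_identity)
            domains.append((NIFX_LIKE, pos + 1, pos + len(seg)))
            parts.append(seg)
            pos += len(seg)

        sequence = _apply_noise(rng, "".join(parts), protected,
                                config.substitution_rate)
        record = ProteinRecord(id=record_id, sequence=sequence,
                               description=f"synthetic {label}")
        if ablate is None or not match_fingerprint(record, fp).passed:
            break
    else:
        raise RuntimeError("could not generate a fingerprint-failing decoy")

    truth = TruthEntry(record_id, "", "", label, tuple(motif_starts),
                       tuple(sorted(domains, key=lambda d: d[1])))
    return record, truth


def generate_contaminant(
    config: SyntheticConfig,
    rng: np.random.Generator,
    record_id: str = "syn",
    fingerprint: Optional[Fingerprint] = None,
) -> tuple[ProteinRecord, TruthEntry]:
    """A NifX-only record guaranteed to fail the six-motif fingerprint."""
    fp = fingerprint or default_fingerprint()
    nifx_tpl, _ = _templates()
    for _ in range(1000):
        lead = _spacer(rng, config)
        seg = _mutated_copy(rng, nifx_tpl, config.domain_identity)
        tail = _spacer(rng, config)
        sequence = lead + seg + tail
        record = ProteinRecord(id=record_id, sequence=sequence,
                               description="synthetic CONTAMINANT")
        if not match_fingerprint(record, fp).passed:
            domains = ((NIFX_LIKE, len(lead) + 1, len(lead) + len(seg)),)
            truth = TruthEntry(record_id, "", "", CONTAMINANT, (), domains)
            return record, truth
    raise RuntimeError("could not generate a fingerprint-failing contaminant")


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full labelled dataset: records, taxonomy rows and truth table.

    Within each group, ``contaminant_fraction`` of the records are NifX-only
    contaminants (count rounded half up); the remainder are split across the
    three architectures by largest-remainder rounding of the configured
    proportions.  Identical configs and seeds give byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    fp = default_fingerprint()
    records: list[ProteinRecord] = []
    taxonomy: list[TaxonomyRecord] = []
    truth: list[TruthEntry] = []

    for spec in config.groups:
        n_cont = _round_half_up(spec.n_records * config.contaminant_fraction)
        n_nifb = spec.n_records - n_cont
        counts = largest_remainder_counts(n_nifb, spec.proportions)
        serial = 0
        for label, count in zip(NIFB_LABELS, counts):
            for _ in range(count):
                serial += 1
                rid = f"{spec.group}_{serial:03d}"
                rec, tr = generate_nifb_record(config, label, rng, rid, fp)
                records.append(rec)
                truth.append(TruthEntry(rid, spec.superkingdom, spec.group,
                                        tr.label, tr.motif_starts, tr.domains))
                taxonomy.append(TaxonomyRecord(rid, spec.superkingdom,
                                               spec.group))
        for _ in range(n_cont):
            serial += 1
            rid = f"{spec.group}_{serial:03d}"
            rec, tr = generate_contaminant(config, rng, rid, fp)
            records.append(rec)
            truth.append(TruthEntry(rid, spec.superkingdom, spec.group,
                                    tr.label, tr.motif_starts, tr.domains))
            taxonomy.append(TaxonomyRecord(rid, spec.superkingdom, spec.group))

    return SyntheticDataset(records=records, taxonomy=taxonomy, truth=truth)
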