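"""Deterministic small computations: mass, in-silico PCR, translation, growth.

These mirror the bookkeeping steps of a cloning-and-characterization
workflow: the theoretical average mass of a protein from its sequence, the
amplicon produced by a primer pair on a template (including 5' primer tails,
as in real PCR), standard-code translation of a coding sequence, and the
exponential growth-rate constant ln2 / t_d from a doubling time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

NUCLEOTIDES = frozenset("ACGT")

#: Default number of 3'-terminal primer bases required to anneal exactly.
DEFAULT_ANNEAL_LEN = 15


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'.

    The reverse primer anneals to the plus strand's complement, i.e. its
    reverse complement appears on the plus strand.
    """

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{name} primer must be non-empty")
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise ValueError(f"{name} primer has invalid bases {sorted(bad)}")


@dataclass(frozen=True)
class Amplicon:
    """A PCR product anchored on the template plus strand.

    ``start``..``end`` (1-based, inclusive) delimit the annealed span on the
    template; ``sequence`` is the template slice over that span, and
    ``full_product`` additionally carries the primers' non-annealing 5'
    tails, so ``len(sequence) == end - start + 1 <= len(full_product)``.
    """

    sequence: str
    start: int
    end: int
    full_product: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GrowthMeasurement:
    """A doubling time (hours) and the implied exponential rate constant."""

    t_d: float

    @property
    def rate(self) -> float:
        return growth_rate(self.t_d)


def average_mass(sequence: str) -> float:
    """Theoretical average (not monoisotopic) mass in daltons.

    Sum of standard average residue masses plus one water; undefined for an
    empty sequence or one containing the unknown residue code ``X``.
    """
    if not sequence or "X" in sequence:
        raise ValueError("mass undefined: empty or X-containing sequence")
    return float(molecular_weight(sequence, seq_type="protein",
                                  monoisotopic=False))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _find_unique(template: str, site: str, primer_name: str) -> int:
    """0-based position of the single occurrence of ``site``; error otherwise."""
    first = template.find(site)
    if first < 0 or template.find(site, first + 1) >= 0:
        raise ValueError(f"primer site not unique: {primer_name} primer")
    return first


def insilico_pcr(template: str, primers: PrimerPair,
                 anneal_len: int = DEFAULT_ANNEAL_LEN) -> Amplicon:
    """Amplify the template with a primer pair.

    The 3'-terminal ``anneal_len`` bases of the forward primer must occur
    exactly once on the plus strand, and likewise the reverse primer's
    reverse complement.  Annealing is extended beyond the required core as
    far as the primer keeps matching the template, so the reported span
    covers the full annealed footprint; any remaining 5' extension is a tail
    carried only by ``full_product``.
    """
    if anneal_len < 12:
        raise ValueError("anneal_len must be at least 12")
    template = template.upper()
    fwd, rev = primers.forward.upper(), primers.reverse.upper()
    if len(fwd) < anneal_len or len(rev) < anneal_len:
        raise ValueError("primer shorter than anneal_len")

    # forward: 3'-terminal core on the plus strand, extended 5'-ward
    f_core = fwd[-anneal_len:]
    f_pos = _find_unique(template, f_core, "forward")
    m = anneal_len
    while (m < len(fwd) and f_pos - (m - anneal_len) - 1 >= 0
           and template[f_pos - (m - anneal_len) - 1] == fwd[-(m + 1)]):
        m += 1
    f_start = f_pos - (m - anneal_len)          # 0-based anneal start
    f_tail = fwd[: len(fwd) - m]

    # reverse: its reverse complement lies on the plus strand; the primer's
    # 3'-terminal core maps to the leftmost bases of that region
    rc = _revcomp(rev)
    r_core = rc[:anneal_len]
    r_pos = _find_unique(template, r_core, "reverse")
    k = anneal_len
    while (k < len(rc) and r_pos + k < len(template)
           and template[r_pos + k] == rc[k]):
        k += 1
    r_end = r_pos + k - 1                       # 0-based anneal end
    r_tail = rc[k:]                             # revcomp of the 5' tail

    if r_end <= f_start:
        raise ValueError("primer sites do not define a forward amplicon")
    core_seq = template[f_start : r_end + 1]
    return Amplicon(
        sequence=core_seq,
        start=f_start + 1,
        end=r_end + 1,
        full_product=f_tail + core_seq + r_tail,
    )


def translate(cds: str) -> str:
    """Standard-code translation; a trailing stop is stripped.

    Raises on a length not divisible by three and on an internal stop codon
    (reported with its 1-based codon index).
    """
    cds = cds.upper()
    if not cds or len(cds) % 3 != 0:
        raise ValueError("incomplete codon: length not divisible by 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"premature stop at codon {protein.index('*') + 1}")
    return protein


def growth_rate(t_d: float) -> float:
    """Exponential growth-rate constant ln2 / t_d (per hour)."""
    if t_d <= 0:
        raise ValueError("invalid doubling time")
    return math.log(2) / t_d


# ---------------------------------------------------------------------------
# Surrogate template for the NifB_Ko C-terminal truncation
# ---------------------------------------------------------------------------

#: The published oligonucleotides that amplify the nifB_Ko ΔC variant.  The
#: forward primer carries an NdeI tail before the start codon; the reverse
#: primer appends nine histidine codons and a stop before an XhoI tail, so
#: the product encodes the 327 N-terminal NifB_Ko residues plus a His9 tag.
NIFB_KO_DC_FORWARD = "CCCCATATGACTACTTCCTGCTCCTCTTTTTCTGGCGGC"
NIFB_KO_DC_REVERSE = (
    "GGGCTCGAGTCAATGATGATGATGATGATGATGATGATGCGCGGGTCGCAATGCTGGCGTGCAG"
)


def nifb_ko_dc_primers() -> PrimerPair:
    """The primer pair defining the nifB_Ko ΔC truncation."""
    return PrimerPair(NIFB_KO_DC_FORWARD, NIFB_KO_DC_REVERSE)


def truncation_surrogate(seed: int = 0) -> tuple[str, PrimerPair, str]:
    """Synthetic stand-in for the nifB_Ko expression-plasmid template.

    The real template (a plasmid carrying the 1404-nt nifB_Ko coding
    sequence) is not bundled; this builds a synthetic 1404-nt CDS whose
    primer-facing ends are dictated by the published oligonucleotides — the
    forward primer's annealing region opens the CDS and the reverse primer's
    native annealing region ends at codon 327 — with seeded random non-stop
    codons in between.  Returns ``(template, primers, full_cds)``: amplifying
    the template with the primers yields a 981-nt native span that, completed
    by the primer-encoded nine-histidine tract, forms a 1008-nt coding region
    (336 residues), while the full CDS translates to 468 residues.
    """
    import numpy as np

    primers = nifb_ko_dc_primers()
    rc = _revcomp(primers.reverse)
    his_idx = rc.find("CAT" * 9)
    head = primers.forward[primers.forward.index("ATGACT") :]  # 33 nt, 11 codons
    native_tail = rc[:his_idx]                                 # 25 nt
    mid_len = 981 - len(head) - len(native_tail)

    rng = np.random.default_rng(seed)
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if a + b + c not in ("TAA", "TAG", "TGA")]

    def random_nt(n: int) -> str:
        s = "".join(codons[i] for i in rng.integers(0, len(codons),
                                                    size=n // 3 + 1))
        return s[:n]

    for _ in range(100):
        native = head + random_nt(mid_len) + native_tail        # 981 nt
        truncated_cds = native + "CAT" * 9                      # 1008 nt
        try:
            translate(truncated_cds)
        except ValueError:
            continue  # a random junction codon formed a stop; redraw
        break
    else:
        raise RuntimeError("could not build a stop-free surrogate CDS")

    # remainder of the full-length CDS: codon-aligned, non-stop, and opening
    # with 'A' so reverse-primer annealing cannot extend past codon 327
    full_cds = native + "AAA" + "".join(
        codons[i] for i in rng.integers(0, len(codons), size=140)
    )
    template = "G" * 20 + full_cds + "TAA" + "G" * 20
    return template, primers, full_cds
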