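"""In-silico PCR: locate primer pairs on transcript sequences.

A pair amplifies when the forward primer matches the plus strand and the
reverse primer's reverse complement matches the plus strand downstream of
it; the product runs from the first base of the forward site through the
last base of the reverse-complement site, inclusive.  Coordinates in
reports are 1-based inclusive (GenBank convention).  Matching is exact by
default; when mismatches are allowed they are never permitted in the
3'-terminal three bases of either primer, because polymerase extension
requires a matched 3' end.  IUPAC ambiguity codes in primers match their
degenerate base sets.

Templates are sense-strand transcripts, so only the plus strand is searched
by default; ``both_strands=True`` additionally scans the reverse complement
(genomic use).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .errors import ValidationError
from .qpcr_data import IUPAC_DNA, PrimerPair

#: IUPAC code -> set of concrete bases it stands for
_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

#: 3'-terminal bases of a primer where mismatches are never tolerated
THREE_PRIME_CLAMP = 3


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted product; coordinates 1-based inclusive on the plus strand."""

    sequence_id: str
    start: int              # 5' end of the forward primer site
    end: int                # plus-strand position of the reverse primer's 5' end
    length_bp: int          # end - start + 1
    fwd_mismatches: int
    rev_mismatches: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.length_bp != self.end - self.start + 1:
            raise ValidationError("inconsistent amplicon coordinates")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _mismatches(primer: str, window: str, max_mismatches: int) -> Optional[int]:
    """Mismatch count of primer vs window, or None if it exceeds the budget
    or touches the 3'-terminal clamp (the last THREE_PRIME_CLAMP primer bases)."""
    clamp_from = len(primer) - THREE_PRIME_CLAMP
    count = 0
    for i, (p, t) in enumerate(zip(primer, window)):
        if t in _IUPAC_SETS.get(p, ()):  # primer code matches template base
            continue
        if i >= clamp_from:
            return None
        count += 1
        if count > max_mismatches:
            return None
    return count


def _site_scan(primer: str, sequence: str, max_mismatches: int,
               clamp_at_end: bool) -> list[tuple[int, int]]:
    """All 0-based start positions where primer aligns; returns (pos, mm).

    ``clamp_at_end`` selects which end of the aligned window corresponds to
    the primer's 3' terminus (True for a plus-strand forward primer; False
    for a reverse primer scanned as its reverse complement, whose 3' end
    maps to the window's *first* bases).
    """
    probe = primer if clamp_at_end else primer[::-1]
    hits = []
    for pos in range(len(sequence) - len(primer) + 1):
        window = sequence[pos:pos + len(primer)]
        probe_window = window if clamp_at_end else window[::-1]
        mm = _mismatches(probe, probe_window, max_mismatches)
        if mm is not None:
            hits.append((pos, mm))
    return hits


def find_amplicons(pair: PrimerPair, sequence: str, *,
                   sequence_id: str = "",
                   max_mismatches: int = 0,
                   max_product_bp: int = 2000,
                   both_strands: bool = False) -> list[AmpliconHit]:
    """All predicted products of a primer pair on one template.

    Every pairing of a forward site with a downstream, non-overlapping
    reverse-complement site whose product is at most ``max_product_bp`` is
    reported, sorted by start.  No hit is an empty list, not an error.
    """
    sequence = sequence.upper().replace("U", "T")
    bad = set(sequence) - IUPAC_DNA
    if bad:
        raise ValidationError(f"template has non-IUPAC characters {sorted(bad)}")

    rev_rc = reverse_complement(pair.reverse)
    hits: list[AmpliconHit] = []
    fwd_sites = _site_scan(pair.forward, sequence, max_mismatches, clamp_at_end=True)
    rev_sites = _site_scan(rev_rc, sequence, max_mismatches, clamp_at_end=False)
    for f_pos, f_mm in fwd_sites:
        for r_pos, r_mm in rev_sites:
            if r_pos < f_pos + len(pair.forward):   # sites must not overlap
                continue
            end0 = r_pos + len(rev_rc) - 1
            length = end0 - f_pos + 1
            if length > max_product_bp:
                continue
            hits.append(AmpliconHit(
                sequence_id=sequence_id, start=f_pos + 1, end=end0 + 1,
                length_bp=length, fwd_mismatches=f_mm, rev_mismatches=r_mm))

    if both_strands:
        rc_seq = reverse_complement(sequence)
        for hit in find_amplicons(pair, rc_seq, sequence_id=sequence_id,
                                  max_mismatches=max_mismatches,
                                  max_product_bp=max_product_bp,
                                  both_strands=False):
            n = len(sequence)
            hits.append(AmpliconHit(
                sequence_id=sequence_id,
                start=n - hit.end + 1, end=n - hit.start + 1,
                length_bp=hit.length_bp,
                fwd_mismatches=hit.fwd_mismatches,
                rev_mismatches=hit.rev_mismatches, strand="-"))

    hits.sort(key=lambda h: (h.start, h.end))
    return hits


@dataclass(frozen=True)
class PanelResult:
    """Validation outcome for one primer pair against a sequence set."""

    pair_name: str
    status: str                     # "pass" | "fail" | "ambiguous" | "not_found"
    n_hits: int
    observed_lengths: tuple[int, ...]
    expected_product_bp: Optional[int]
    sequence_ids: tuple[str, ...]


def validate_panel(pairs: Sequence[PrimerPair],
                   sequences: Sequence[tuple[str, str]], *,
                   max_mismatches: int = 0,
                   max_product_bp: int = 2000) -> list[PanelResult]:
    """Check each primer pair against a FASTA-derived (id, sequence) set.

    Pass requires exactly one amplicon across all sequences whose length
    equals the pair's expected_product_bp.  Multiple hits are flagged
    ambiguous; no hits, not_found; a single hit of the wrong length (or a
    single hit with no stated expectation to check), fail is only for the
    length mismatch — with no expectation the single-hit outcome is "pass"
    with the observed length reported.
    """
    results = []
    for pair in pairs:
        all_hits = []
        for seq_id, seq in sequences:
            all_hits.extend(find_amplicons(pair, seq, sequence_id=seq_id,
                                           max_mismatches=max_mismatches,
                                           max_product_bp=max_product_bp))
        lengths = tuple(h.length_bp for h in all_hits)
        seq_ids = tuple(h.sequence_id for h in all_hits)
        if not all_hits:
            status = "not_found"
        elif len(all_hits) > 1:
            status = "ambiguous"
        elif pair.expected_product_bp is None:
            status = "pass"
        else:
            status = ("pass" if lengths[0] == pair.expected_product_bp else "fail")
        results.append(PanelResult(
            pair_name=pair.name, status=status, n_hits=len(all_hits),
            observed_lengths=lengths,
            expected_product_bp=pair.expected_product_bp,
            sequence_ids=seq_ids))
    return results
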