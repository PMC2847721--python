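"""In-silico PCR: primer matching, amplicon coordinates, panel validation.

GenBank transcript records are not bundled; templates here are synthetic
sequences with primer sites planted at known positions, including stand-ins
built from the published primer sequences of the BDNF/IL8/TNNC1 assays with
spacer lengths chosen to reproduce the reported product sizes.
"""

import numpy as np
import pytest

from earnorm import (PrimerPair, ValidationError, find_amplicons,
                     validate_panel)
from earnorm.insilico_pcr import reverse_complement

FWD = "ATGCGTACGTTAGCATCGGA"   # 20-mer
REV = "TTGCACGATCGGATACCAGT"   # 20-mer (written 5'->3', as ordered)


def template(spacer: str, prefix: str = "", suffix: str = "") -> str:
    """Plus-strand template: FWD + spacer + revcomp(REV), padded."""
    return prefix + FWD + spacer + reverse_complement(REV) + suffix


def random_spacer(n: int, seed: int = 7) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindAmplicons:
    def test_constructed_60_base_amplicon(self):
        pair = PrimerPair("p", FWD, REV)
        seq = template(random_spacer(20))
        (hit,) = find_amplicons(pair, seq)
        assert (hit.start, hit.end, hit.length_bp) == (1, 60, 60)
        assert hit.fwd_mismatches == hit.rev_mismatches == 0

    def test_padding_shifts_coordinates_one_based(self):
        pair = PrimerPair("p", FWD, REV)
        seq = template(random_spacer(20), prefix="AAAA", suffix="GGGG")
        (hit,) = find_amplicons(pair, seq)
        assert (hit.start, hit.end, hit.length_bp) == (5, 64, 60)
        # coordinates really delimit the product, inclusive
        assert len(seq[hit.start - 1:hit.end]) == hit.length_bp

    def test_absent_primer_gives_empty_list(self):
        pair = PrimerPair("p", FWD, REV)
        assert find_amplicons(pair, random_spacer(200)) == []

    def test_reverse_complement_symmetry(self):
        """Swapping primers on the reverse-complement template mirrors the hit."""
        pair = PrimerPair("p", FWD, REV)
        seq = template(random_spacer(33), prefix="CATG", suffix="TTAA")
        (hit,) = find_amplicons(pair, seq)
        mirrored_pair = PrimerPair("pm", REV, FWD)
        (mhit,) = find_amplicons(mirrored_pair, reverse_complement(seq))
        assert mhit.length_bp == hit.length_bp
        assert mhit.start == len(seq) - hit.end + 1

    def test_planted_site_found_exactly_once(self):
        pair = PrimerPair("p", FWD, REV)
        seq = template(random_spacer(50), prefix=random_spacer(40, seed=1),
                       suffix=random_spacer(40, seed=2))
        assert len(find_amplicons(pair, seq)) == 1

    def test_product_over_size_cap_not_reported(self):
        pair = PrimerPair("p", FWD, REV)
        seq = template(random_spacer(100))
        assert find_amplicons(pair, seq, max_product_bp=120) == []
        assert len(find_amplicons(pair, seq, max_product_bp=140)) == 1

    def test_iupac_degenerate_primer_base_matches_set(self):
        fwd_deg = FWD[:10] + "N" + FWD[11:]       # N matches anything
        pair = PrimerPair("p", fwd_deg, REV)
        (hit,) = find_amplicons(pair, template(random_spacer(20)))
        assert hit.fwd_mismatches == 0            # degenerate match, not mismatch

    def test_internal_mismatch_tolerated_when_budgeted(self):
        seq = template(random_spacer(20))
        mutated = FWD[:5] + ("A" if FWD[5] != "A" else "C") + FWD[6:]
        pair = PrimerPair("p", mutated, REV)
        assert find_amplicons(pair, seq) == []
        (hit,) = find_amplicons(pair, seq, max_mismatches=1)
        assert hit.fwd_mismatches == 1

    def test_three_prime_clamp_never_tolerates_mismatch(self):
        seq = template(random_spacer(20))
        mutated = FWD[:-1] + ("A" if FWD[-1] != "A" else "C")
        pair = PrimerPair("p", mutated, REV)
        assert find_amplicons(pair, seq, max_mismatches=3) == []

    def test_both_strands_flag_finds_minus_strand_product(self):
        pair = PrimerPair("p", FWD, REV)
        seq = reverse_complement(template(random_spacer(20)))
        assert find_amplicons(pair, seq) == []
        (hit,) = find_amplicons(pair, seq, both_strands=True)
        assert hit.strand == "-" and hit.length_bp == 60

    def test_non_iupac_template_rejected(self):
        with pytest.raises(ValidationError):
            find_amplicons(PrimerPair("p", FWD, REV), "ACGTJ" * 20)


# printed primer sequences of the published assays
BDNF = PrimerPair("BDNF", "TAACGGCGGCAGACAAAAAGA",
                  "GAAGTATTGCTTCAGTTGGCCT", expected_product_bp=101)
IL8 = PrimerPair("IL8", "CCATCTCACTGTGTGTAAACATGAC",
                 "TCCACTCTCAATCACTCTCAGTTCT", expected_product_bp=194)
TNNC1 = PrimerPair("TNNC1", "TGCAGGAGATGATCGATGAGGTG",
                   "TGCGGAAGAGGTCAGACAGCTC", expected_product_bp=138)


def synthetic_transcript(pair: PrimerPair, product_bp: int, seed: int) -> str:
    """Synthetic stand-in template yielding the given product size."""
    spacer = product_bp - len(pair.forward) - len(pair.reverse)
    assert spacer >= 0
    return (random_spacer(30, seed=seed)
            + pair.forward + random_spacer(spacer, seed=seed + 1)
            + reverse_complement(pair.reverse)
            + random_spacer(30, seed=seed + 2))


class TestValidatePanel:
    def test_published_assays_on_synthetic_templates(self):
        """Panel reproduces the assays' product sizes on planted templates."""
        seqs = [("synth_BDNF", synthetic_transcript(BDNF, 101, seed=11)),
                ("synth_IL8", synthetic_transcript(IL8, 194, seed=22)),
                ("synth_TNNC1", synthetic_transcript(TNNC1, 138, seed=33))]
        results = {r.pair_name: r for r in validate_panel([BDNF, IL8, TNNC1], seqs)}
        assert results["BDNF"].observed_lengths == (101,)
        assert results["IL8"].observed_lengths == (194,)
        assert results["TNNC1"].observed_lengths == (138,)
        assert all(r.status == "pass" for r in results.values())

    def test_expectation_off_by_one_fails_with_lengths_reported(self):
        pair = PrimerPair("p", FWD, REV, expected_product_bp=61)
        result, = validate_panel([pair], [("t", template(random_spacer(20)))])
        assert result.status == "fail"
        assert result.observed_lengths == (60,)
        assert result.expected_product_bp == 61

    def test_multiple_hits_flagged_ambiguous(self):
        pair = PrimerPair("p", FWD, REV, expected_product_bp=60)
        double = template(random_spacer(20)) + "AAAA" + template(random_spacer(20))
        result, = validate_panel([pair], [("t", double)])
        assert result.status == "ambiguous"

    def test_absent_pair_reported_not_found(self):
        pair = PrimerPair("p", FWD, REV, expected_product_bp=60)
        result, = validate_panel([pair], [("t", random_spacer(100))])
        assert result.status == "not_found"
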