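from collections import Counter

import numpy as np
import pytest

from taxoprime import (
    DesignConstraints,
    PlantedWindow,
    PanelConfig,
    combined_mismatch_probability,
    design_primer_pairs,
    dimer_score,
    find_discriminative_windows,
    generate_genus_panel,
    generate_template_with_sites,
    hairpin_check,
    melting_temperature,
    revcomp,
    score_3prime_discrimination,
)
from taxoprime.core_io import build_common_sequence
from taxoprime.primer_design import gc_content

from conftest import make_alignment


class TestMeltingTemperature:
    @pytest.mark.parametrize(
        "seq,expect",
        [("GC", 8), ("ATAT", 8), ("AAAATCTATGGGGCTGGGTC", 60)],
    )
    def test_wallace(self, seq, expect):
        assert melting_temperature(seq) == expect

    def test_gc_method(self):
        # 20-mer with 10 G+C
        seq = "A" * 10 + "G" * 10
        assert melting_temperature(seq, "gc") == pytest.approx(64.9 + 41 * (10 - 16.4) / 20)

    def test_rejects_ambiguity(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGN")
        with pytest.raises(ValueError):
            melting_temperature("")


class TestHairpin:
    def test_homopolymer_has_none(self):
        assert not hairpin_check("AAAAAAAAAAAA").found

    def test_stem_loop_detected(self):
        r = hairpin_check("GGGGCAAATGCCCC")
        assert r.found and r.stem_length == 5  # GGGGC pairs GCCCC around AAAT

    def test_min_loop_respected(self):
        assert hairpin_check("GGGGTTTCCCC").found  # 4-stem, 3-loop
        assert not hairpin_check("GGGGTTCCCC").found  # loop of 2 is too tight

    def test_impossible_stem_length(self):
        assert not hairpin_check("GGGCCC", min_stem=4).found


class TestDimer:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ("AAAA", "AAAA", 0),  # A does not pair A
            ("ACGT", "ACGT", 4),  # palindrome: full antiparallel duplex
            ("AAAA", "CCCC", 0),
            ("GGTCTTCTGTTAACAGTTGT", "GGTCTTCTGTTAACAGTTGT", 10),  # CTGTTAACAG palindrome
        ],
    )
    def test_examples(self, a, b, expect):
        assert dimer_score(a, b) == expect

    def test_self_default(self):
        assert dimer_score("ACGT") == 4


# ---------------------------------------------------------------------------
# Window discovery


def brute_force_windows(aln, genus, length_range, min_diff, min_cons):
    """Independent exhaustive re-derivation of the window definition."""
    rows: dict[str, list[str]] = {}
    for r in aln.records:
        rows.setdefault(r.genus, []).append(r.sequence)
    tgt = rows[genus]
    others = {g: s for g, s in rows.items() if g != genus}
    n = aln.length
    res = []
    for L in range(length_range[0], min(length_range[1], n) + 1):
        for s in range(n - L + 1):
            cons = []
            for c in range(s, s + L):
                cnt = Counter(t[c] for t in tgt)
                top = max(cnt.values())
                cons.append(sorted(b for b, k in cnt.items() if k == top)[0])
            cons = "".join(cons)
            if set(cons) - set("ACGT"):
                continue
            matches = sum(t[c] == cons[c - s] for t in tgt for c in range(s, s + L))
            conservation = 100 * matches / (len(tgt) * L)
            if conservation < min_cons:
                continue
            dc = {}
            ok = True
            for g, seqs in others.items():
                D = min(sum(q[c] != cons[c - s] for c in range(s, s + L)) for q in seqs)
                dc[g] = D
                if D < min_diff:
                    ok = False
            if ok:
                res.append((s, s + L, min(dc.values())))
    res.sort(key=lambda w: (-w[2], w[0], w[1]))
    return res


class TestWindowSearch:
    def test_identical_genera_yield_nothing(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        aln = make_alignment(
            [("A", "x", "1", seq), ("A", "x", "2", seq), ("B", "y", "1", seq)]
        )
        assert find_discriminative_windows(aln, "A", (18, 20), 1) == []

    def test_errors(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        aln = make_alignment([("A", "x", "1", seq), ("B", "y", "1", seq)])
        with pytest.raises(ValueError, match="absent"):
            find_discriminative_windows(aln, "Z", (18, 20), 1)
        short = make_alignment([("A", "x", "1", "ACGT"), ("B", "y", "1", "ACGT")])
        with pytest.raises(ValueError, match="shorter"):
            find_discriminative_windows(short, "A", (18, 20), 1)

    def test_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for trial in range(6):
            ncols = int(rng.integers(25, 61))
            rows = []
            base = rng.choice(list("ACGT"), size=ncols)
            for g in ("GA", "GB", "GC"):
                anc = base.copy()
                mut = rng.random(ncols) < 0.15
                anc[mut] = rng.choice(list("ACGT"), size=mut.sum())
                for s in range(2):
                    member = anc.copy()
                    mut2 = rng.random(ncols) < 0.03
                    member[mut2] = rng.choice(list("ACGT"), size=mut2.sum())
                    rows.append((g, "sp", f"s{s}", "".join(member)))
            aln = make_alignment(rows)
            got = find_discriminative_windows(aln, "GA", (18, 22), 2, 85.0)
            expect = brute_force_windows(aln, "GA", (18, 22), 2, 85.0)
            assert [(w.start, w.end, w.min_diff) for w in got] == expect

    def test_near_identical_regime_needs_low_min_diff(self):
        # two genera differing by 1-3 bases anywhere: windows exist at
        # min_diff 1 but not at min_diff 4
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACGT"), size=60))
        other = list(base)
        other[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[20]]
        other[45] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[45]]
        aln = make_alignment(
            [("Raphi", "med", "1", base), ("Cyl", "rac", "1", "".join(other))]
        )
        assert find_discriminative_windows(aln, "Raphi", (18, 25), 1)
        assert find_discriminative_windows(aln, "Raphi", (18, 25), 4) == []

    def test_planted_window_recovered_across_seeds(self):
        # a saturated discriminative region (every planted column differs
        # from every other genus) must dominate the ranking: windows shifted
        # off the plant strictly lose differences
        for seed in range(20):
            cfg = PanelConfig(
                seed=seed,
                n_genera=4,
                seqs_per_genus=3,
                length=400,
                within_genus_divergence=0.04,
                between_genus_divergence=0.05,
                planted_windows=(PlantedWindow(150, 170, "GenusA", 18),),
            )
            aln, _ = generate_genus_panel(cfg)
            ws = find_discriminative_windows(aln, "GenusA", (20, 20), 10, 95.0)
            assert ws, f"seed {seed}: no window found"
            top = ws[0]
            overlap = max(0, min(top.end, 170) - max(top.start, 150))
            assert overlap / len(top) >= 0.9, f"seed {seed}: overlap {overlap}/{len(top)}"

    def test_reverse_complement_involution(self):
        # with identical target rows (tie-free consensus) window coordinates
        # mirror exactly under reverse complement
        cfg = PanelConfig(
            seed=3,
            n_genera=3,
            seqs_per_genus=2,
            length=200,
            within_genus_divergence=0.0,
            between_genus_divergence=0.2,
        )
        aln, _ = generate_genus_panel(cfg)
        fwd = find_discriminative_windows(aln, "GenusA", (18, 20), 3, 99.0)
        flipped = make_alignment(
            [(r.genus, r.species, r.strain, revcomp(r.sequence)) for r in aln.records]
        )
        rev = find_discriminative_windows(flipped, "GenusA", (18, 20), 3, 99.0)
        n = aln.length
        assert {(n - w.end, n - w.start) for w in rev} == {(w.start, w.end) for w in fwd}


class TestPairDesign:
    def _planted_panel(self):
        cfg = PanelConfig(
            seed=17,
            n_genera=3,
            seqs_per_genus=3,
            length=500,
            within_genus_divergence=0.01,
            between_genus_divergence=0.12,
            planted_windows=(
                PlantedWindow(100, 120, "GenusA", 6, "forward"),
                PlantedWindow(433, 453, "GenusA", 6, "reverse"),
            ),
        )
        return generate_genus_panel(cfg)

    def test_planted_pair_product_size(self):
        aln, truth = self._planted_panel()
        ws = find_discriminative_windows(aln, "GenusA", (20, 20), 4, 99.0)
        fwd = [w for w in ws if w.start >= 100 and w.end <= 120]
        rev = [w for w in ws if w.start >= 433 and w.end <= 453]
        assert fwd and rev
        for w in fwd:
            w.strand_role = "forward"
        for w in rev:
            w.strand_role = "reverse"
        cons = build_common_sequence(
            [r for r in aln.records if r.genus == "GenusA"], policy="first"
        ).sequence
        res = design_primer_pairs(fwd + rev, cons, DesignConstraints(length=(20, 20), product_size=(300, 400)))
        assert res.pairs
        assert any(p.product_size == 353 for p in res.pairs)  # 453 - 100
        top = res.pairs[0]
        assert top.recommended_annealing in (51, 53, 55, 57, 59)
        assert top.reverse.sequence == revcomp(top.reverse.window.consensus[
            top.reverse.start - top.reverse.window.start:
            top.reverse.start - top.reverse.window.start + top.reverse.length])

    def test_impossible_tm_yields_rejection_tallies(self):
        aln, _ = self._planted_panel()
        ws = find_discriminative_windows(aln, "GenusA", (20, 20), 4, 99.0)
        for w in ws:
            w.strand_role = "forward" if w.start < 250 else "reverse"
        cons = build_common_sequence(
            [r for r in aln.records if r.genus == "GenusA"], policy="first"
        ).sequence
        res = design_primer_pairs(
            ws, cons, DesignConstraints(length=(20, 20), tm_range=(1.0, 2.0))
        )
        assert res.pairs == []
        assert res.rejections["tm"] > 0
        assert res.rejections.most_common(1)[0][0] == "tm"

    def test_determinism(self):
        aln, _ = self._planted_panel()
        ws = find_discriminative_windows(aln, "GenusA", (20, 20), 4, 99.0)
        for w in ws:
            w.strand_role = "forward" if w.start < 250 else "reverse"
        cons = build_common_sequence(
            [r for r in aln.records if r.genus == "GenusA"], policy="first"
        ).sequence
        a = design_primer_pairs(ws, cons, DesignConstraints(length=(20, 20), product_size=(300, 400)))
        b = design_primer_pairs(ws, cons, DesignConstraints(length=(20, 20), product_size=(300, 400)))
        assert [(p.forward.sequence, p.reverse.sequence, p.product_size) for p in a.pairs] == [
            (p.forward.sequence, p.reverse.sequence, p.product_size) for p in b.pairs
        ]


class TestThreePrimeDiscrimination:
    FWD = "TACCCTCAAGCCAGAAATGG"
    REV = "TGGTCTTCTGTTAATAACTGC"

    def _templates(self, mismatches=()):
        on, _ = generate_template_with_sites(self.FWD, self.REV, 120, seed=5)
        off, _ = generate_template_with_sites(self.FWD, self.REV, 120, seed=5, mismatches=mismatches)
        return on, off

    def test_identical_offtarget_scores_zero(self):
        on, off = self._templates()
        prof = score_3prime_discrimination(self.REV, on, off)
        assert prof.positions == [] and prof.combined == 0.0

    def test_terminal_mismatch_only(self):
        on, off = self._templates([("reverse", 1)])
        prof = score_3prime_discrimination(self.REV, on, off)
        assert prof.positions == [1]
        assert prof.per_position_probability == {1: 22.5}
        assert prof.combined == pytest.approx(22.5)

    def test_positions_1_4_5_combined(self):
        on, off = self._templates([("reverse", 1), ("reverse", 4), ("reverse", 5)])
        prof = score_3prime_discrimination(self.REV, on, off)
        assert prof.positions == [1, 4, 5]
        assert prof.combined == pytest.approx(64.5, abs=0.05)

    def test_unknown_positions_flagged_not_invented(self):
        on, off = self._templates([("reverse", 1), ("reverse", 3)])
        prof = score_3prime_discrimination(self.REV, on, off)
        assert prof.unknown_positions == [3]
        assert prof.combined == pytest.approx(22.5)

    def test_combined_monotone_as_positions_added(self):
        subsets = [[1], [1, 4], [1, 4, 5]]
        vals = [combined_mismatch_probability(s).combined for s in subsets]
        assert vals[0] < vals[1] < vals[2]

    def test_primer_must_bind_target_perfectly(self):
        on, off = self._templates([("reverse", 1)])
        with pytest.raises(ValueError, match="perfect"):
            score_3prime_discrimination(self.REV, off, on)

    def test_custom_probability_table(self):
        prof = combined_mismatch_probability([1, 2], {1: 50.0, 2: 50.0})
        assert prof.combined == pytest.approx(75.0)


class TestPublishedPrimerRegression:
    def test_all_pass_default_screens(self, primer_table):
        c = DesignConstraints()
        for p in primer_table:
            assert len(p.sequence) >= 18
            assert not hairpin_check(p.sequence, min_stem=c.max_hairpin_stem + 1).found, p.name
            assert dimer_score(p.sequence) <= c.max_self_dimer_run, p.name
            # GC content within screening range
            assert c.gc_range[0] <= gc_content(p.sequence) <= c.gc_range[1], p.name

    def test_raphi_cyl_reverse_primers_discriminate_at_terminus(self, primer_table):
        prim = {p.name: p.sequence for p in primer_table}
        raphi_r, cyl_r = prim["Raphi-rpoC1-R"], prim["Cyl-rpoC1-R"]
        # synthetic homolog pair: one backbone carrying each genus's reverse
        # binding site, aligned without indels
        pad = "G" * (len(raphi_r) - len(cyl_r))
        aligned_cyl = pad + cyl_r
        site_on = revcomp(raphi_r)
        site_off = revcomp(raphi_r[: len(pad)] + aligned_cyl[len(pad):])
        rng_flank = "ATGC" * 10
        on = rng_flank + site_on + rng_flank
        off = rng_flank + site_off + rng_flank
        prof = score_3prime_discrimination(raphi_r, on, off)
        assert 1 in prof.positions  # terminal mismatch present
        assert {4, 5} <= set(prof.positions)
        assert prof.combined > 60.0
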