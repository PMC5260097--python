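"""Compatibility, effective length, EM estimation, FPKM arithmetic."""

import math

import numpy as np
import pytest

from locquant import (
    FragLenModel,
    build_bundle_index,
    correct_fpkm,
    effective_length,
    em_quantify,
    fetch_fragments,
    infer_msb,
    is_compatible,
    quantify_in_msb,
)
from locquant.quantify import (
    _relative_fpkm,
    compatibility_matrix,
    estimate_frag_len,
    quantify_sample,
)

from conftest import make_frag, make_tx

FLM = FragLenModel(200.0, 50.0)


def oracle_compatible(frag, tx):
    """Independent base-level checker: every aligned base exonic, every
    splice gap exactly a transcript intron."""
    if frag.chrom != tx.chrom:
        return False
    exonic = set()
    for e in tx.exons:
        exonic.update(range(e.start, e.end))
    for b in frag.blocks:
        if not set(range(b.start, b.end)) <= exonic:
            return False
    introns = {(i.start, i.end) for i in tx.introns}
    return all((i.start, i.end) in introns for i in frag.introns)


class TestCompatibility:
    def test_block_containment(self):
        tx = make_tx("T", [(100, 200)])
        assert is_compatible(make_frag("f", [(100, 150)]), tx)
        assert not is_compatible(make_frag("f", [(150, 250)]), tx)

    def test_junction_mismatch(self):
        tx = make_tx("T", [(100, 200), (310, 400)])  # intron (200, 310)
        good = make_frag("f", [(180, 200), (310, 330)], introns=[(200, 310)])
        bad = make_frag("g", [(180, 200), (300, 330)], introns=[(200, 300)])
        assert is_compatible(good, tx)
        assert not is_compatible(bad, tx)

    def test_different_chrom_false(self):
        tx = make_tx("T", [(0, 500)], chrom="chr2")
        assert not is_compatible(make_frag("f", [(0, 100)]), tx)

    def test_inner_mate_gap_may_span_skipped_exon(self):
        # paired fragment whose unsequenced gap silently crosses an intron
        tx = make_tx("T", [(0, 100), (200, 300)])
        frag = make_frag("f", [(50, 100), (200, 250)], paired=True)
        assert is_compatible(frag, tx)

    def test_matches_brute_force_on_simdata(self, small_sim):
        frags = fetch_fragments(small_sim.alignment_path)[::25]
        txs = list(small_sim.annotation.transcripts.values())
        mat = compatibility_matrix(frags, txs)
        for i, f in enumerate(frags):
            for j, t in enumerate(txs):
                assert mat.compatible[i, j] == oracle_compatible(f, t), (
                    f.fragment_id,
                    t.transcript_id,
                )
        # scalar API agrees with the vectorized matrix
        for i, f in enumerate(frags[:40]):
            for j, t in enumerate(txs):
                assert is_compatible(f, t) == mat.compatible[i, j]

    def test_source_isoform_always_compatible(self, small_sim):
        frags = fetch_fragments(small_sim.alignment_path)
        txs = list(small_sim.annotation.transcripts.values())
        mat = compatibility_matrix(frags, txs)
        # every simulated fragment is compatible with at least one isoform
        # of the locus it was drawn from (its source, by construction)
        assert mat.compatible.any(axis=1).all()


class TestEffectiveLength:
    @pytest.mark.parametrize(
        "length,mean,expect", [(1000, 200, 801), (150, 200, 1), (200, 200, 1)]
    )
    def test_formula(self, length, mean, expect):
        tx = make_tx("T", [(0, length)])
        assert effective_length(tx, FragLenModel(mean, 50.0)) == expect


class TestEM:
    def test_single_transcript_gets_all(self):
        tx = make_tx("T", [(0, 1000)])
        frags = [make_frag(f"f{i}", [(i * 50, i * 50 + 200)], paired=True) for i in range(10)]
        out = em_quantify(frags, [tx], FLM)
        assert out["T"] == pytest.approx(10.0, abs=1e-9)

    def test_disjoint_sets_reduce_to_counting(self):
        a = make_tx("A", [(0, 1000)])
        b = make_tx("B", [(5000, 6000)])
        frags = [make_frag(f"a{i}", [(100 + i, 300 + i)], paired=True) for i in range(6)]
        frags += [make_frag(f"b{i}", [(5100 + i, 5300 + i)], paired=True) for i in range(4)]
        out = em_quantify(frags, [a, b], FLM)
        assert out["A"] == pytest.approx(6.0, abs=1e-9)
        assert out["B"] == pytest.approx(4.0, abs=1e-9)

    def test_zero_assignable_fragments(self):
        tx = make_tx("T", [(0, 1000)])
        frags = [make_frag("f", [(5000, 5200)])]
        assert em_quantify(frags, [tx], FLM) == {"T": 0.0}

    def test_identical_transcripts_split_equally(self):
        a = make_tx("A", [(0, 1000)])
        b = make_tx("B", [(0, 1000)])
        frags = [make_frag(f"f{i}", [(i * 40, i * 40 + 200)], paired=True) for i in range(9)]
        out = em_quantify(frags, [a, b], FLM)
        assert out["A"] == pytest.approx(out["B"], rel=1e-9)
        assert out["A"] + out["B"] == pytest.approx(9.0, abs=1e-6)

    @staticmethod
    def _mle_instance():
        """Two length-1000 isoforms sharing exon territory.

        A is one exon [0,1000); B skips [500,700) and continues to 1200.
        Returns (transcripts, fragments, per-fragment (wA, wB) weights for
        the grid-search oracle, computed here independently).
        """
        A = make_tx("A", [(0, 1000)])
        B = make_tx("B", [(0, 500), (700, 1200)])

        def w(ell, L=1000, mean=200.0, sd=50.0):
            if ell is None:
                return 0.0
            pdf = math.exp(-0.5 * ((ell - mean) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
            return pdf / max(1, L - ell + 1)

        frags, weights = [], []
        for i in range(6):  # unique to A: crosses B's missing region
            frags.append(make_frag(f"a{i}", [(460 + i, 740 + i)], paired=True))
            weights.append((w(280), 0.0))
        for i in range(4):  # unique to B: spliced over B's intron
            frags.append(
                make_frag(
                    f"b{i}", [(450 - i, 500), (700, 750 + i)], introns=[(500, 700)], paired=True
                )
            )
            weights.append((0.0, w(100 + 2 * i)))
        for i in range(8):  # ambiguous: inner mate gap spans B's intron
            frags.append(make_frag(f"s{i}", [(430 - i, 500), (700, 750)], paired=True))
            # implied length: genomic span on A; minus the 200 bp intron on B
            weights.append((w(320 + i), w(120 + i)))
        return [A, B], frags, weights

    def test_em_matches_grid_search_mle(self):
        txs, frags, weights = self._mle_instance()
        out = em_quantify(frags, txs, FLM)
        n = len(frags)
        theta_hat = out["A"] / n

        grid = np.arange(0.0, 1.0 + 1e-12, 1e-4)
        ll = np.zeros_like(grid)
        for wa, wb in weights:
            ll += np.log(np.maximum(wa * grid + wb * (1 - grid), 1e-300))
        theta_star = grid[np.argmax(ll)]
        assert theta_hat == pytest.approx(theta_star, abs=1e-3)

    def test_conservation_and_monotone_likelihood(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n_tx = int(rng.integers(1, 5))
            txs = []
            for j in range(n_tx):
                L = int(rng.integers(400, 2000))
                s = int(rng.integers(0, 500))
                txs.append(make_tx(f"T{j}", [(s, s + L)]))
            frags = []
            for i in range(int(rng.integers(1, 60))):
                src = txs[int(rng.integers(0, n_tx))]
                fl = int(rng.integers(100, 350))
                fl = min(fl, src.length)
                st = int(rng.integers(0, src.length - fl + 1))
                g = src.exons[0].start
                frags.append(make_frag(f"f{i}", [(g + st, g + st + fl)], paired=True))
            out, trace = em_quantify(frags, txs, FLM, return_loglik_trace=True)
            mat = compatibility_matrix(frags, txs).compatible
            n_assignable = int(mat.any(axis=1).sum())
            assert sum(out.values()) == pytest.approx(n_assignable, abs=1e-6)
            assert all(b - a >= -1e-9 for a, b in zip(trace, trace[1:]))

    def test_scale_invariance_under_duplication(self):
        txs, frags, _ = self._mle_instance()
        out1 = em_quantify(frags, txs, FLM)
        doubled = frags + [
            make_frag(f.fragment_id + "_dup", [(b.start, b.end) for b in f.blocks],
                      introns=[(i.start, i.end) for i in f.introns], paired=f.paired)
            for f in frags
        ]
        out2 = em_quantify(doubled, txs, FLM)
        for tid in out1:
            assert out2[tid] == pytest.approx(2 * out1[tid], rel=1e-6)
        # relative FPKM is unchanged when counts and local totals both double
        eff = 801
        assert _relative_fpkm(out2["A"], eff, 2 * len(frags)) == pytest.approx(
            _relative_fpkm(out1["A"], eff, len(frags)), rel=1e-9
        )


class TestFpkm:
    def test_relative_fpkm_closed_form(self):
        # 10 fragments, 1 kb effective length, local total 1000 -> 10,000
        assert _relative_fpkm(10.0, 1000, 1000) == pytest.approx(10000.0)

    def test_zero_denominators(self):
        assert _relative_fpkm(0.0, 1000, 0) == 0.0
        assert _relative_fpkm(5.0, 0, 100) == 0.0

    def test_quantrecord_invariant_via_msb(self, small_sim):
        ann = small_sim.annotation
        idx = build_bundle_index(small_sim.alignment_path, ann)
        tid = sorted(ann.transcripts)[0]
        reduced = ann.without([tid])
        msb = infer_msb(ann[tid], idx, reduced)
        for rec in quantify_in_msb(msb, small_sim.alignment_path, idx):
            if rec.local_fragment_total and rec.effective_length:
                assert rec.relative_fpkm == pytest.approx(
                    rec.expected_fragments
                    / (
                        (rec.effective_length / 1000)
                        * (rec.local_fragment_total / 1e6)
                    )
                )


class TestFragLenEstimation:
    def test_fallback_when_too_few_unique(self):
        tx = make_tx("T", [(0, 1000)])
        frags = [make_frag(f"f{i}", [(0, 200)], paired=True) for i in range(3)]
        flm = estimate_frag_len(frags, [tx])
        assert flm.source == "fixed"
        assert (flm.mean, flm.sd) == (200.0, 50.0)

    def test_recovers_simulated_distribution(self, small_sim):
        frags = fetch_fragments(small_sim.alignment_path)
        txs = list(small_sim.annotation.transcripts.values())
        flm = estimate_frag_len(frags, txs)
        assert flm.source == "estimated"
        assert flm.mean == pytest.approx(200.0, abs=15.0)
        assert flm.sd == pytest.approx(50.0, abs=15.0)


class TestLocalGlobalEquivalence:
    def test_msb_local_equals_whole_file(self, small_sim):
        """The locality claim: quantifying inside the MSB reproduces the
        whole-transcriptome result for a held-out transcript exactly."""
        ann = small_sim.annotation
        frags = fetch_fragments(small_sim.alignment_path)
        glob = quantify_sample(ann, fragments=frags)
        for tid in sorted(ann.transcripts)[:8]:
            tx = ann[tid]
            reduced = ann.without([tid])
            idx = build_bundle_index(None, reduced, fragments=frags, sample_id="s")
            msb = infer_msb(tx, idx, reduced)
            local = quantify_in_msb(msb, small_sim.alignment_path, idx)[0]
            lc, gc = correct_fpkm(local), correct_fpkm(glob[tid])
            assert lc == pytest.approx(gc, rel=1e-6, abs=1e-9)
            assert local.expected_fragments == pytest.approx(
                glob[tid].expected_fragments, rel=1e-6, abs=1e-9
            )
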