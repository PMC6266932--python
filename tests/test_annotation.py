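"""Annotation transfer gates, description similarity and domain agreement."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from orthonet.annotation import (
    DomainProfile,
    FunctionalAssignment,
    compare_domains,
    description_bin,
    description_similarity,
    read_domain_profiles,
    read_reference_metadata,
    summarize_description_bins,
    transfer_annotation,
)
from orthonet.io import SequenceLevel
from orthonet.orthology import OrthologyRelation
from conftest import make_hit

T = SequenceLevel.TRANSCRIPT
META = {
    "R1": ("Photosystem II D2 protein", ("3.2.1.4",)),
    "R2": ("Pectate lyase", ()),
}


def ref_hit(q, acc, pident=95.0, cover=0.92, score=100.0, evalue=1e-50):
    qlen = 1000
    end = int(qlen * cover)
    return make_hit(
        q, acc, level=T, pident=pident, score=score, evalue=evalue,
        qlen=qlen, slen=qlen, q_iv=[(1, end)], s_iv=[(1, end)],
    )


class TestTransferAnnotation:
    def test_passing_both_gates_assigns(self):
        out = transfer_annotation([ref_hit("t1", "R1", 95.0, 0.92)], META)
        assert out["t1"].description == "Photosystem II D2 protein"
        assert out["t1"].ec_numbers == ("3.2.1.4",)

    @pytest.mark.parametrize(
        "pident,cover", [(95.0, 0.80), (85.0, 0.92)],
        ids=["coverage-gate", "identity-gate"],
    )
    def test_failing_either_gate_leaves_gene_unassigned(self, pident, cover):
        assert transfer_annotation([ref_hit("t1", "R1", pident, cover)], META) == {}

    def test_best_hit_wins_with_tie_breaks(self):
        hits = [
            ref_hit("t1", "R1", score=100.0, evalue=1e-50),
            ref_hit("t1", "R2", score=200.0, evalue=1e-40),
        ]
        out = transfer_annotation(hits, META)
        assert out["t1"].source_accession == "R2"

    def test_missing_accession_metadata_is_an_error(self):
        with pytest.raises(KeyError, match="RX"):
            transfer_annotation([ref_hit("t1", "RX")], META)

    def test_output_never_violates_the_90_90_invariant(self):
        rng = random.Random(41)
        hits = [
            ref_hit(
                f"t{rng.randrange(10)}",
                rng.choice(["R1", "R2"]),
                pident=rng.uniform(70, 100),
                cover=rng.uniform(0.5, 1.0),
                score=rng.uniform(50, 500),
            )
            for _ in range(100)
        ]
        for a in transfer_annotation(hits, META).values():
            assert a.percent_identity >= 90.0
            assert a.percent_coverage >= 90.0

    def test_random_tables_match_filter_then_argmax_oracle(self):
        rng = random.Random(6)
        hits = [
            ref_hit(
                f"t{rng.randrange(8)}",
                rng.choice(["R1", "R2"]),
                pident=rng.choice([85.0, 92.0, 99.0]),
                cover=rng.choice([0.7, 0.91, 0.99]),
                score=rng.choice([50.0, 100.0, 150.0]),
                evalue=rng.choice([1e-60, 1e-40]),
            )
            for _ in range(120)
        ]
        result = transfer_annotation(hits, META)
        # oracle: group HSPs per (query, accession) — coverage is the union
        # of aligned query positions, identity/score/e-value come from the
        # best-scoring HSP — then gate at 90/90 and take the argmax
        groups = {}
        for h in hits:
            groups.setdefault((h.query_id, h.subject_id), []).append(h)
        oracle = {}
        for (q, acc), group in groups.items():
            best = min(group, key=lambda h: (-h.bit_score, h.e_value))
            covered = set()
            for h in group:
                for lo, hi in h.query_intervals:
                    covered.update(range(lo, hi + 1))
            cov = 100.0 * len(covered) / 1000
            if best.percent_identity < 90.0 or cov < 90.0:
                continue
            key = (-best.bit_score, best.e_value, acc)
            if q not in oracle or key < oracle[q][0]:
                oracle[q] = (key, acc)
        assert {g: a.source_accession for g, a in result.items()} == {
            g: acc for g, (_, acc) in oracle.items()
        }

    def test_gene_mapping_applied(self):
        out = transfer_annotation(
            [ref_hit("t1", "R1")], META, gene_of_query={"t1": "G1"}
        )
        assert set(out) == {"G1"}


class TestDescriptionSimilarity:
    def test_identical_descriptions_hit_the_100_bin(self):
        sim = description_similarity(
            "Photosystem II D2 protein", "Photosystem II D2 protein"
        )
        assert sim == 100.0
        assert description_bin(sim) == "100"

    def test_like_suffix_variant_lands_in_80_99(self):
        """33-char LCS over mean length 35.5 gives 93%."""
        sim = description_similarity(
            "E3 ubiquitin-protein ligase RING1",
            "E3 ubiquitin-protein ligase RING1-like",
        )
        assert round(sim, 1) == 93.0
        assert description_bin(sim) == "80-99"

    def test_qualifier_and_suffix_loss_lands_in_60_79(self):
        """13-char LCS over mean length 19.5 gives 66.7%."""
        sim = description_similarity("Probable pectate lyase P59", "Pectate lyase")
        assert round(sim, 1) == 66.7
        assert description_bin(sim) == "60-79"

    def test_empty_description_rejected(self):
        with pytest.raises(ValueError):
            description_similarity("", "Pectate lyase")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="abcdef ", min_size=1, max_size=20).filter(str.strip),
        st.text(alphabet="abcdef ", min_size=1, max_size=20).filter(str.strip),
    )
    def test_symmetric_and_matches_dp_oracle(self, a, b):
        def lcs(x, y):
            import functools

            @functools.lru_cache(maxsize=None)
            def rec(i, j):
                if i == 0 or j == 0:
                    return 0
                if x[i - 1] == y[j - 1]:
                    return rec(i - 1, j - 1) + 1
                return max(rec(i - 1, j), rec(i, j - 1))

            return rec(len(x), len(y))

        import re

        fa = re.sub(r"\s+", " ", a.strip()).casefold()
        fb = re.sub(r"\s+", " ", b.strip()).casefold()
        expected = 100.0 * lcs(fa, fb) / ((len(fa) + len(fb)) / 2)
        assert description_similarity(a, b) == pytest.approx(expected)
        assert description_similarity(a, b) == pytest.approx(
            description_similarity(b, a)
        )

    def test_100_iff_folded_identical_and_0_iff_disjoint_alphabets(self):
        assert description_similarity("Heat  Shock", "heat shock") == 100.0
        assert description_similarity("abc", "xyz") == 0.0


class TestCompareDomains:
    def prof(self, *domains):
        return DomainProfile("g", frozenset(domains))

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("D1", "D2"), ("D1", "D2"), "ALL_SHARED"),
            (("D1", "D2"), ("D2", "D3"), "SOME_SHARED"),
            (("D1",), ("D2",), "NONE_SHARED"),
            (("D1",), (), "NONE_SHARED"),
        ],
    )
    def test_agreement_classes(self, a, b, expected):
        assert compare_domains(self.prof(*a), self.prof(*b)) == expected

    def test_symmetric(self):
        a, b = self.prof("D1", "D2"), self.prof("D2", "D3")
        assert compare_domains(a, b) == compare_domains(b, a)

    def test_both_empty_is_an_error(self):
        with pytest.raises(ValueError, match="skip"):
            compare_domains(self.prof(), self.prof())


class TestDescriptionBinsSummary:
    def _assign(self, gene, desc):
        return FunctionalAssignment(gene, desc, "R1", (), 95.0, 95.0)

    def test_identical_pair_counted_in_100_bin(self):
        rels = [OrthologyRelation("a1", "b1", frozenset({T}), {})]
        out = summarize_description_bins(
            rels,
            {"a1": self._assign("a1", "Pectate lyase")},
            {"b1": self._assign("b1", "Pectate lyase")},
        )
        assert out["histogram"]["100"] == 1 and out["skipped"] == 0

    def test_unannotated_relations_skipped_and_totals_balance(self):
        rels = [
            OrthologyRelation("a1", "b1", frozenset({T}), {}),
            OrthologyRelation("a2", "b2", frozenset({T}), {}),
        ]
        out = summarize_description_bins(rels, {}, {})
        assert sum(out["histogram"].values()) == 0
        assert out["skipped"] == len(rels)

    def test_random_fixture_matches_per_pair_oracle(self):
        rng = random.Random(3)
        descs = ["Pectate lyase", "Pectate lyase-like", "Photosystem II D2 protein"]
        rels, amap, bmap = [], {}, {}
        for i in range(30):
            a, b = f"a{i}", f"b{i}"
            rels.append(OrthologyRelation(a, b, frozenset({T}), {}))
            if rng.random() < 0.8:
                amap[a] = self._assign(a, rng.choice(descs))
            if rng.random() < 0.8:
                bmap[b] = self._assign(b, rng.choice(descs))
        out = summarize_description_bins(rels, amap, bmap)
        oracle = {label: 0 for label in out["histogram"]}
        skipped = 0
        for r in rels:
            if r.gene_a not in amap or r.gene_b not in bmap:
                skipped += 1
                continue
            oracle[
                description_bin(
                    description_similarity(
                        amap[r.gene_a].description, bmap[r.gene_b].description
                    )
                )
            ] += 1
        assert out == {"histogram": oracle, "skipped": skipped}
        assert sum(oracle.values()) + skipped == len(rels)


def test_reference_metadata_and_domain_readers(tmp_path):
    meta = tmp_path / "meta.tsv"
    meta.write_text("R1\tPectate lyase\t4.2.2.2;4.2.2.10\nR2\tExpansin-A4\t\n")
    parsed = read_reference_metadata(meta)
    assert parsed["R1"] == ("Pectate lyase", ("4.2.2.2", "4.2.2.10"))
    assert parsed["R2"] == ("Expansin-A4", ())

    ipr = tmp_path / "domains.tsv"
    cols = ["p1", "md5", "300", "Pfam", "PF00001", "desc", "1", "300",
            "1e-30", "T", "01-01-2020", "IPR000001", "entry", "-", "-"]
    no_ipr = list(cols)
    no_ipr[4], no_ipr[11] = "PF00002", "-"
    ipr.write_text("\t".join(cols) + "\n" + "\t".join(no_ipr) + "\n")
    profiles = read_domain_profiles(ipr, {"p1": "G1"})
    assert profiles["G1"].domains == {"IPR000001", "PF00002"}
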