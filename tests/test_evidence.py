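"""Homology-hit filtering, partitioning, grouping and evidence channels."""

import numpy as np
import pytest

import domainseg as ds
from domainseg.evidence import (
    SEQUENCE,
    STRUCTURE,
    hit_sort_key,
    read_dali_equivalences,
    read_hhr,
    read_hits_tsv,
    scaled_score,
    write_hits_tsv,
)


def _hit(source, rid, score, q_residues, h_start=1):
    mapping = {q: h_start + i for i, q in enumerate(sorted(q_residues))}
    return ds.HitAlignment(source, rid, score, mapping)


class TestPartition:
    def test_clean_bisection(self):
        hit = _hit(SEQUENCE, "chain", 90.0, range(1, 201))
        defs = [
            ds.ReferenceDomainDefinition("A", ((1, 100),)),
            ds.ReferenceDomainDefinition("B", ((101, 200),)),
        ]
        parts = ds.partition_hit_by_reference_domains(hit, defs)
        assert [p.ref_domain_id for p in parts] == ["A", "B"]
        assert [len(p.mapping) for p in parts] == [100, 100]
        assert all(p.score == 90.0 for p in parts)

    def test_containment(self):
        hit = _hit(SEQUENCE, "chain", 50.0, range(50, 61))
        defs = [ds.ReferenceDomainDefinition("A", ((1, 100),))]
        (part,) = ds.partition_hit_by_reference_domains(hit, defs)
        assert len(part.mapping) == 11

    def test_empty_defs(self):
        hit = _hit(SEQUENCE, "chain", 50.0, range(1, 10))
        assert ds.partition_hit_by_reference_domains(hit, []) == []

    def test_random_fixture_matches_membership_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(10, 80))
            qs = rng.choice(np.arange(1, 200), size=n, replace=False)
            mapping = dict(zip(qs.tolist(), rng.integers(1, 300, size=n).tolist()))
            hit = ds.HitAlignment(STRUCTURE, "chain", 8.0, mapping)
            defs = []
            for k, (s, e) in enumerate([(1, 90), (91, 180), (200, 260)]):
                defs.append(ds.ReferenceDomainDefinition(f"d{k}", ((s, e),)))
            parts = ds.partition_hit_by_reference_domains(hit, defs)
            got = {p.ref_domain_id: len(p.mapping) for p in parts}
            for d in defs:
                expect = sum(
                    1 for h in mapping.values() if any(s <= h <= e for s, e in d.chain_ranges)
                )
                assert got.get(d.domain_id, 0) == expect


class TestIterativeAlignment:
    def _model(self, L):
        coords = [np.array([[3.8 * i, 0.0, 0.0]]) for i in range(L)]
        return ds.ChainModel(np.arange(1, L + 1), "A" * L, coords, np.full(L, 90.0))

    def test_aligner_finding_nothing(self):
        out = ds.iterative_structural_alignment(self._model(100), "h", lambda r, h: None)
        assert out == []

    def test_tandem_duplicate_transcript(self):
        # the aligner finds residues 1-100 first, then 101-200, then nothing
        def aligner(remaining, hit_id):
            remaining = set(remaining)
            if set(range(1, 101)) <= remaining:
                return _hit(STRUCTURE, hit_id, 20.0, range(1, 101))
            if set(range(101, 201)) <= remaining:
                return _hit(STRUCTURE, hit_id, 18.0, range(101, 201))
            return None

        out = ds.iterative_structural_alignment(self._model(200), "h", aligner)
        assert len(out) == 2
        covs = [set(h.mapping) for h in out]
        assert covs[0] & covs[1] == set()
        assert covs[0] | covs[1] == set(range(1, 201))

    def test_min_remaining_stops_loop(self):
        calls = []

        def aligner(remaining, hit_id):
            calls.append(len(remaining))
            return _hit(STRUCTURE, hit_id, 9.0, list(remaining)[:90])

        ds.iterative_structural_alignment(self._model(100), "h", aligner, min_remaining=20)
        # 100 -> aligned 90 -> 10 left < 20 -> stop
        assert calls == [100]

    def test_aligner_failure_reports_iteration(self):
        def aligner(remaining, hit_id):
            raise OSError("backend crashed")

        with pytest.raises(RuntimeError, match="iteration 1"):
            ds.iterative_structural_alignment(self._model(50), "h", aligner)


class TestFilterAcceptable:
    def test_zero_thresholds_are_identity(self):
        hits = [_hit(SEQUENCE, "a", 1.0, range(1, 3)), _hit(STRUCTURE, "b", 0.5, range(1, 3))]
        cfg = ds.AcceptabilityConfig(0, 0, 0, 0)
        assert ds.filter_acceptable(hits, cfg) == hits

    def test_low_probability_removed(self):
        hits = [_hit(SEQUENCE, "a", 10.0, range(1, 50))]
        cfg = ds.AcceptabilityConfig(seq_min_probability=20.0)
        assert ds.filter_acceptable(hits, cfg) == []

    def test_mixed_fixture_matches_predicate_oracle(self):
        rng = np.random.default_rng(1)
        cfg = ds.AcceptabilityConfig()
        hits = []
        for _ in range(20):
            src = SEQUENCE if rng.random() < 0.5 else STRUCTURE
            score = float(rng.uniform(0, 100 if src == SEQUENCE else 40))
            n = int(rng.integers(1, 60))
            hits.append(_hit(src, "x", score, range(1, n + 1)))
        got = ds.filter_acceptable(hits, cfg)
        expect = [
            h
            for h in hits
            if (
                (h.source == SEQUENCE and h.score >= 20 and len(h.mapping) >= 10)
                or (h.source == STRUCTURE and h.score >= 2 and len(h.mapping) >= 20)
            )
        ]
        assert got == expect


class TestGroupHits:
    def test_identical_coverage_two_groups(self):
        a = _hit(SEQUENCE, "a", 90.0, range(1, 51))
        b = _hit(SEQUENCE, "b", 80.0, range(1, 51))
        groups = ds.group_hits([a, b])
        assert [len(g.hits) for g in groups] == [1, 1]

    def test_disjoint_coverage_one_group(self):
        a = _hit(SEQUENCE, "a", 90.0, range(1, 51))
        b = _hit(SEQUENCE, "b", 80.0, range(60, 111))
        groups = ds.group_hits([a, b])
        assert [len(g.hits) for g in groups] == [2]

    def test_random_hits_match_greedy_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(30):
            hits = []
            for k in range(10):
                s = int(rng.integers(1, 150))
                e = s + int(rng.integers(10, 80))
                hits.append(_hit(SEQUENCE, f"h{k}", float(rng.uniform(20, 99)), range(s, e)))
            got = ds.group_hits(hits, overlap_frac=0.20)
            # literal transcription of the greedy admission rule
            ordered = sorted(hits, key=hit_sort_key)
            oracle: list[list] = []
            covs: list[set] = []
            for h in ordered:
                c = set(h.mapping)
                for gi, gc in enumerate(covs):
                    ov = len(c & gc)
                    if ov < 0.2 * len(c) or ov < 0.2 * len(gc):
                        oracle[gi].append(h)
                        covs[gi] = gc | c
                        break
                else:
                    oracle.append([h])
                    covs.append(set(c))
            assert [[h.ref_domain_id for h in g.hits] for g in got] == [
                [h.ref_domain_id for h in g] for g in oracle
            ]

    def test_groups_partition_input(self):
        rng = np.random.default_rng(3)
        hits = [
            _hit(STRUCTURE, f"h{k}", float(rng.uniform(2, 40)), range(int(rng.integers(1, 100)), int(rng.integers(100, 200))))
            for k in range(12)
        ]
        groups = ds.group_hits(hits)
        flat = [h for g in groups for h in g.hits]
        assert sorted(h.ref_domain_id for h in flat) == sorted(h.ref_domain_id for h in hits)


class TestEvidenceChannels:
    def test_single_hit_block(self):
        hit = _hit(SEQUENCE, "a", 90.0, range(1, 51))
        (pm,) = ds.build_evidence_channels(ds.group_hits([hit]), L=100)
        assert pm.values[0, 49] == pytest.approx(0.9)
        assert pm.values[0, 50] == 0.0
        assert pm.values[60, 60] == 0.0
        assert np.allclose(pm.values, pm.values.T)

    def test_group_elementwise_max(self):
        a = _hit(SEQUENCE, "a", 80.0, range(1, 41))
        b = _hit(SEQUENCE, "b", 60.0, range(30, 71))
        groups = [ds.EvidenceGroup([a, b])]
        (pm,) = ds.build_evidence_channels(groups, L=80)
        assert pm.values[30, 35] == pytest.approx(0.8)  # overlap takes the max
        assert pm.values[50, 60] == pytest.approx(0.6)

    def test_channel_cap(self):
        groups = [
            ds.EvidenceGroup([_hit(SEQUENCE, f"h{k}", 99.0 - k, range(1 + 10 * k, 9 + 10 * k))])
            for k in range(15)
        ]
        channels = ds.build_evidence_channels(groups, L=200, max_channels=10)
        assert len(channels) == 10
        # the ten best by leading score
        assert channels[0].values.max() == pytest.approx(0.99)

    def test_structure_score_squash(self):
        hit = _hit(STRUCTURE, "s", 10.0, range(1, 30))
        assert scaled_score(hit) == pytest.approx(0.5)
        assert 0 <= scaled_score(_hit(STRUCTURE, "s", 1000.0, range(1, 3))) < 1


class TestReaders:
    def test_hits_tsv_round_trip(self, tmp_path):
        hits = [
            _hit(SEQUENCE, "a", 88.5, range(3, 30)),
            _hit(STRUCTURE, "b", 12.0, range(10, 60)),
        ]
        write_hits_tsv(hits, tmp_path / "h.tsv")
        again = read_hits_tsv(tmp_path / "h.tsv")
        assert [(h.source, h.ref_domain_id, h.score, h.mapping) for h in again] == [
            (h.source, h.ref_domain_id, h.score, h.mapping) for h in hits
        ]

    def test_domain_definitions_tsv(self, tmp_path):
        (tmp_path / "d.tsv").write_text("domain_id\trange\nD1\tA:1-100,A:150-200\n")
        (d,) = ds.evidence.read_domain_definitions_tsv(tmp_path / "d.tsv")
        assert d.chain_ranges == ((1, 100), (150, 200))
        assert 150 in d and 149 not in d

    def test_hhr_alignment_blocks(self, tmp_path):
        text = """\
Query q1
Match_columns 40

No 1
>refdom1 some description
Probab=97.30  E-value=1e-30  Score=100.0

Q q1             5 ACD-EF   9 (40)
T refdom1        1 ACDGEF   6 (6)

No 2
>refdom2
Probab=45.00  E-value=0.1  Score=20.0

Q q1            20 GHI  22 (40)
T refdom2        7 GHI   9 (12)
"""
        (tmp_path / "x.hhr").write_text(text)
        hits = read_hhr(tmp_path / "x.hhr")
        assert len(hits) == 2
        h1, h2 = hits
        assert h1.ref_domain_id == "refdom1" and h1.score == 97.30
        # gap in the query sequence: hit residue 4 (G) is unaligned
        assert h1.mapping == {5: 1, 6: 2, 7: 3, 8: 5, 9: 6}
        assert h2.mapping == {20: 7, 21: 8, 22: 9}

    def test_dali_equivalences(self, tmp_path):
        (tmp_path / "d.txt").write_text(
            ">dom1 Z=12.5\n1-10 = 21-30\n15-17 = 31-33\n>dom2 Z=3.0\n40-44 = 1-5\n"
        )
        hits = read_dali_equivalences(tmp_path / "d.txt")
        assert [h.ref_domain_id for h in hits] == ["dom1", "dom2"]
        assert hits[0].score == 12.5
        assert hits[0].mapping[15] == 31
        assert len(hits[0].mapping) == 13
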