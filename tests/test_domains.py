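"""Architecture calling, terminus mining, clustering and custom HMMs."""

import numpy as np
import pytest

from rbpdetect.domains import (
    Cluster,
    TerminusPart,
    align_cluster,
    call_architecture,
    construct_custom_hmms,
    extract_parts,
    find_one_sided,
    greedy_cluster,
    is_rbp_by_domains,
    known_rbp_domain_names,
    pairwise_identity,
    scan_proteins,
)
from rbpdetect.profile_hmm import DomainHit
from rbpdetect.synthetic import ModularFixtureSpec, gen_modular_proteins, random_protein


def _hit(start, end, name="fam", target="t"):
    return DomainHit(name, target, start, end, 50.0)


class TestArchitecture:
    def test_boundary_residue_200_is_n_terminal(self):
        arch = call_architecture("t", [_hit(200, 320)])
        assert len(arch.n_terminal_domains) == 1
        assert arch.c_terminal_domains == []

    def test_boundary_residue_201_is_c_terminal(self):
        arch = call_architecture("t", [_hit(201, 320)])
        assert arch.n_terminal_domains == []
        assert len(arch.c_terminal_domains) == 1

    def test_side_assignment_partitions_hits(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            hits = [_hit(int(s), int(s) + 10, name=f"h{i}")
                    for i, s in enumerate(rng.integers(1, 400, size=6))]
            arch = call_architecture("t", hits)
            assert arch.n_hits == len(hits)
            assert all(h.ali_start <= 200 for h in arch.n_terminal_domains)
            assert all(h.ali_start > 200 for h in arch.c_terminal_domains)

    def test_signature_preserves_n_to_c_order(self):
        arch = call_architecture("t", [_hit(250, 300, "c"), _hit(10, 80, "n")])
        assert arch.signature == ("n", "c")

    def test_detection_rule(self):
        assert not is_rbp_by_domains(call_architecture("t", []))
        assert is_rbp_by_domains(call_architecture("t", [_hit(10, 50)]))
        assert is_rbp_by_domains(call_architecture("t", [_hit(10, 50), _hit(250, 300)]))


class TestOneSided:
    def test_classification(self):
        n_only = call_architecture("a", [_hit(10, 80)])
        c_only = call_architecture("b", [_hit(250, 300)])
        both = call_architecture("c", [_hit(10, 80), _hit(250, 300)])
        none = call_architecture("d", [])
        missing_n, missing_c = find_one_sided([n_only, c_only, both, none])
        assert [a.target_id for a in missing_n] == ["b"]
        assert [a.target_id for a in missing_c] == ["a"]

    def test_extract_parts_conventions(self):
        seqs = {"a": "A" * 800, "b": "C" * 800, "short": "D" * 150}
        missing_c = [call_architecture("a", [_hit(10, 230, target="a")])]
        missing_n = [call_architecture("b", [_hit(250, 400, target="b")]),
                     call_architecture("short", [_hit(110, 150, target="short")])]
        parts, skipped = extract_parts(missing_n, missing_c, seqs)
        by_id = {p.parent_id: p for p in parts}
        # unknown N terminus: first 200 residues, truncated at sequence end
        assert (by_id["b"].start, by_id["b"].end) == (1, 200)
        assert (by_id["short"].start, by_id["short"].end) == (1, 150)
        # unknown C terminus: everything after the last N-terminal hit
        assert (by_id["a"].start, by_id["a"].end) == (231, 800)
        assert by_id["a"].subsequence == "A" * 570
        assert skipped == []

    def test_empty_c_part_is_skipped(self):
        seqs = {"x": "A" * 300}
        missing_c = [call_architecture("x", [_hit(10, 300, target="x")])]
        parts, skipped = extract_parts([], missing_c, seqs)
        assert parts == [] and skipped == ["x"]


def _part(seq, pid="p", side="N"):
    return TerminusPart(pid, side, seq, 1, len(seq))


class TestClustering:
    def test_identical_parts_form_one_cluster(self):
        parts = [_part("ACDEFGHIKL" * 4, pid=f"p{i}") for i in range(5)]
        clusters = greedy_cluster(parts)
        assert len(clusters) == 1 and clusters[0].size == 5

    def test_unrelated_parts_stay_apart(self):
        rng = np.random.default_rng(5)
        parts = [_part(random_protein(rng, 60), pid=f"p{i}") for i in range(4)]
        clusters = greedy_cluster(parts, identity_threshold=0.9)
        assert len(clusters) == 4

    def test_three_mutated_families_cluster_cleanly(self, modular_fixture):
        """Families at ~10% within-family divergence, threshold 0.9."""
        fix = modular_fixture
        rng = np.random.default_rng(17)
        parts = []
        for fam in fix.families:
            if fam.side != "C":
                continue
            for j in range(6):
                parts.append(_part(fam.sample_member(rng), pid=f"{fam.name}_{j}",
                                   side="C"))
        clusters = greedy_cluster(parts, identity_threshold=0.9)
        n_c_fams = sum(f.side == "C" for f in fix.families)
        assert len(clusters) == n_c_fams
        assert sorted(c.size for c in clusters) == [6] * n_c_fams

    def test_clustering_is_a_partition(self, modular_fixture):
        fix = modular_fixture
        rng = np.random.default_rng(23)
        parts = [
            _part(fam.sample_member(rng), pid=f"{fam.name}_{j}", side=fam.side)
            for fam in fix.families for j in range(4)
            if fam.side == "N"
        ]
        clusters = greedy_cluster(parts)
        seen = [m.parent_id for c in clusters for m in c.members]
        assert sorted(seen) == sorted(p.parent_id for p in parts)
        for c in clusters:
            for m in c.members:
                ident = pairwise_identity(
                    m.subsequence, c.representative.subsequence
                )
                assert ident >= c.identity_threshold


class TestAlignCluster:
    def _cluster(self, seqs):
        parts = [_part(s, pid=f"p{i}") for i, s in enumerate(seqs)]
        return Cluster(representative=parts[0], members=parts)

    def test_identical_members_align_gapless(self):
        msa = align_cluster(self._cluster(["ACDEFGHIKL" * 3] * 5))
        assert msa is not None
        assert len(set(msa.sequences)) == 1
        assert "-" not in msa.sequences[0]

    def test_small_cluster_is_skipped(self):
        assert align_cluster(self._cluster(["ACDEFGHIKL" * 3] * 4)) is None

    def test_internal_insertion_creates_one_gap_column(self):
        base = "ACDEFGHIKLMNPQRSTVWY"
        with_ins = base[:10] + "W" + base[10:]
        msa = align_cluster(self._cluster([base] * 4 + [with_ins]))
        assert msa is not None
        assert msa.width == len(base) + 1
        gapped = [row for row in msa.sequences if "-" in row]
        assert len(gapped) == 4  # everyone except the inserted member


class TestCustomHmmPipeline:
    def test_one_hmm_per_withheld_family(self, custom_hmm_run):
        fix, augmented, report = custom_hmm_run
        n_withheld_c = sum(f.side == "C" and not f.known for f in fix.families)
        assert report.n_built["C"] == n_withheld_c
        custom_names = [h.name for h in augmented if h.name.startswith("custom_")]
        assert len(custom_names) == n_withheld_c

    def test_rescan_gains_previously_undetected_orphans(self, custom_hmm_run):
        _, _, report = custom_hmm_run
        assert report.additional_detections > 0

    def test_detection_set_never_shrinks_after_augmentation(self, custom_hmm_run):
        fix, augmented, _ = custom_hmm_run
        before = {
            a.target_id
            for a in scan_proteins(fix.sequences, fix.base_hmms)
            if is_rbp_by_domains(a)
        }
        after = {
            a.target_id
            for a in scan_proteins(fix.sequences, augmented)
            if is_rbp_by_domains(a)
        }
        assert before <= after

    def test_no_one_sided_input_builds_nothing(self, modular_fixture):
        fix = modular_fixture
        known_only = {
            pid: seq for pid, seq in fix.sequences.items()
            if pid.startswith("known_")
        }
        augmented, report = construct_custom_hmms(known_only, fix.base_hmms)
        assert report.n_built == {"N": 0, "C": 0}
        assert len(augmented) == len(fix.base_hmms)


def test_curated_domain_name_config_is_complete():
    names = known_rbp_domain_names()
    assert "Phage_T7_tail" in names["n_terminal"]
    assert "Peptidase_S74" in names["c_terminal"]
    assert len(names["n_terminal"]) + len(names["c_terminal"]) > 25
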