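import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmob.homology import ReferenceSet
from asmob.mhc import (
    DEFAULT_DENYLIST,
    build_network,
    filter_candidates,
    mag_motif_profile,
    scan_motifs,
)
from asmob.records import AnnotationTable, LocalizationTable, ProteinRecord
from asmob.synthetic import make_mhc_protein, motif_block, random_protein, strip_motifs

from .oracles import motif_count_oracle


def _prot(seq, pid="p"):
    return ProteinRecord(id=pid, sequence=seq)


class TestScanMotifs:
    def test_three_planted_motifs(self):
        inv = scan_motifs(_prot("MACAACHAACAACHAACAACHAA"))
        assert inv.motif_count == 3
        assert inv.is_candidate

    def test_overlap_resolved_greedily(self):
        inv = scan_motifs(_prot("CAACHACH"))
        assert inv.motif_count == 1
        assert scan_motifs(_prot("CAACHACH"), overlapping=True).motif_count == 2

    def test_positions_satisfy_motif_invariants(self):
        rng = np.random.default_rng(2)
        seq = strip_motifs(rng, random_protein(rng, 150)) + "GSG" + motif_block(rng, 6)
        inv = scan_motifs(_prot(seq))
        assert inv.motif_count == 6
        for p in inv.motif_positions:
            assert seq[p - 1] == "C" and seq[p + 2] == "C" and seq[p + 3] == "H"
        diffs = np.diff(inv.motif_positions)
        assert (diffs >= 5).all()

    def test_random_sequences_match_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            seq = random_protein(rng, 300)
            inv = scan_motifs(_prot(seq))
            count, positions = motif_count_oracle(seq)
            assert inv.motif_count == count
            assert list(inv.motif_positions) == positions

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        base=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=80),
        extra=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
    )
    def test_appending_residues_never_decreases_count(self, base, extra):
        before = scan_motifs(_prot(base)).motif_count
        after = scan_motifs(_prot(base + extra)).motif_count
        assert after >= before


@pytest.fixture(scope="module")
def seeds_and_candidates(scheme):
    rng = np.random.default_rng(21)
    metal_core = strip_motifs(rng, random_protein(rng, 300))
    nonmetal_core = strip_motifs(rng, random_protein(rng, 300))
    seeds = [
        ReferenceSet(
            family="mhc_metal",
            role="seed_metal",
            members=(
                _prot(make_mhc_protein(rng, metal_core, 88.0, 10), "metal_seed1"),
            ),
        ),
        ReferenceSet(
            family="mhc_nonmetal",
            role="seed_nonmetal",
            members=(
                _prot(make_mhc_protein(rng, nonmetal_core, 88.0, 4), "nonmetal_seed1"),
            ),
        ),
    ]
    metal_cands = [
        _prot(make_mhc_protein(rng, metal_core, 80.0, 8 + i), f"m{i}") for i in range(3)
    ]
    nonmetal_cands = [
        _prot(make_mhc_protein(rng, nonmetal_core, 80.0, 5), f"n{i}") for i in range(2)
    ]
    return seeds, metal_cands, nonmetal_cands


class TestNetwork:
    def test_identical_candidates_share_cluster(self, scheme):
        rng = np.random.default_rng(8)
        seq = make_mhc_protein(rng, strip_motifs(rng, random_protein(rng, 300)), 90.0, 5)
        net = build_network([_prot(seq, "a"), _prot(seq, "b")], [], scheme)
        assert net.cluster_of["a"] == net.cluster_of["b"]

    def test_infinite_cutoff_gives_singletons(self, scheme, seeds_and_candidates):
        seeds, metal, nonmetal = seeds_and_candidates
        net = build_network(metal + nonmetal, seeds, scheme, score_cutoff=float("inf"))
        assert len(net.clusters) == len(metal) + len(nonmetal) + 2

    def test_planted_families_recovered_as_components(self, scheme, seeds_and_candidates):
        seeds, metal, nonmetal = seeds_and_candidates
        net = build_network(metal + nonmetal, seeds, scheme, score_cutoff=67.0)
        metal_clusters = {net.cluster_of[p.id] for p in metal}
        nonmetal_clusters = {net.cluster_of[p.id] for p in nonmetal}
        assert len(metal_clusters) == 1 and len(nonmetal_clusters) == 1
        assert metal_clusters != nonmetal_clusters
        assert net.cluster_of["metal_seed1"] in metal_clusters
        assert net.cluster_of["nonmetal_seed1"] in nonmetal_clusters


class TestFilter:
    def _run(self, scheme, seeds_and_candidates, annotations=None, localizations=None):
        seeds, metal, nonmetal = seeds_and_candidates
        prots = metal + nonmetal
        invs = [scan_motifs(p) for p in prots]
        net = build_network(prots, seeds, scheme, score_cutoff=67.0)
        return filter_candidates(
            invs,
            net,
            AnnotationTable(annotations or {}),
            LocalizationTable(localizations or {}),
        )

    def test_nonmetal_cluster_removed(self, scheme, seeds_and_candidates):
        out = {c.protein_id: c.status for c in self._run(scheme, seeds_and_candidates)}
        assert out["n0"] == out["n1"] == "removed_cluster"
        assert out["m0"] == "retained"

    def test_cytoplasmic_removed(self, scheme, seeds_and_candidates):
        out = {
            c.protein_id: c.status
            for c in self._run(
                scheme, seeds_and_candidates, localizations={"m1": "Cytoplasmic"}
            )
        }
        assert out["m1"] == "removed_cytoplasmic"
        assert out["m0"] == "retained"

    def test_denylist_annotation_fires_before_cluster(self, scheme, seeds_and_candidates):
        out = {
            c.protein_id: c.status
            for c in self._run(scheme, seeds_and_candidates, annotations={"n0": "NrfA"})
        }
        assert out["n0"] == "removed_annotation"
        assert out["n1"] == "removed_cluster"

    def test_below_threshold_wins_over_everything(self, scheme):
        rng = np.random.default_rng(5)
        weak = _prot(strip_motifs(rng, random_protein(rng, 200)) + "GSG" + motif_block(rng, 2), "w")
        out = filter_candidates(
            [scan_motifs(weak)],
            None,
            AnnotationTable({"w": "NrfA"}),
            LocalizationTable({"w": "Cytoplasmic"}),
        )
        assert out[0].status == "below_threshold"

    def test_retained_invariant(self, scheme, seeds_and_candidates):
        for c in self._run(scheme, seeds_and_candidates, localizations={"m2": "Periplasmic"}):
            if c.status == "retained":
                assert c.motif_count >= 3
                assert c.localization != "Cytoplasmic"

    def test_final_retained_set_independent_of_removal_order(self, scheme, seeds_and_candidates):
        """Each removal criterion is a property of the candidate itself, so
        the retained set equals the candidates failing no criterion."""
        seeds, metal, nonmetal = seeds_and_candidates
        prots = metal + nonmetal
        invs = [scan_motifs(p) for p in prots]
        net = build_network(prots, seeds, scheme, score_cutoff=67.0)
        ann = AnnotationTable({"m1": "HAO"})
        loc = LocalizationTable({"m2": "Cytoplasmic"})
        out = filter_candidates(invs, net, ann, loc)
        retained = {c.protein_id for c in out if c.status == "retained"}
        expected = set()
        for inv in invs:
            cl = net.cluster_of[inv.protein_id]
            bad = (
                inv.motif_count < 3
                or (ann.get(inv.protein_id) or "") in DEFAULT_DENYLIST
                or (net.cluster_has_role(cl, "seed_nonmetal") and not net.cluster_has_role(cl, "seed_metal"))
                or loc.get(inv.protein_id) == "Cytoplasmic"
            )
            if not bad:
                expected.add(inv.protein_id)
        assert retained == expected


class TestMagProfile:
    def _cands(self, counts, mag):
        from asmob.mhc import MhcCandidate

        return [
            MhcCandidate(f"{mag}_p{i}", k, 0, "Unknown", "retained")
            for i, k in enumerate(counts)
        ], {f"{mag}_p{i}": mag for i in range(len(counts))}

    def test_flagged_above_fifty(self):
        cands, assignment = self._cands([10, 25, 20], "M1")
        (profile,) = mag_motif_profile(cands, assignment)
        assert profile.total_motifs == 55
        assert profile.flagged

    def test_exactly_fifty_not_flagged(self):
        cands, assignment = self._cands([25, 25], "M1")
        (profile,) = mag_motif_profile(cands, assignment)
        assert profile.total_motifs == 50
        assert not profile.flagged

    def test_empty_mag_total_zero(self):
        (profile,) = mag_motif_profile([], {"x": "M9"})
        assert profile.mag_id == "M9" and profile.total_motifs == 0
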