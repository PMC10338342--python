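import itertools
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from nucaccess import synth
from nucaccess._util import revcomp
from nucaccess.smf import (
    GAP,
    MATCH,
    MISMATCH,
    AmpliconRef,
    BinaryMatrixClustering,
    GchMatrix,
    build_gch_matrix,
    call_gch,
    cluster_binary,
    convert_reference,
    dedup_and_downsample,
    map_full_length,
    merge_pair,
    min_unique_depth,
    protection_profile,
    run_pipeline,
    score_align,
    select_by_primer,
)


def enumeration_oracle(q, t):
    """Max global alignment score by exhaustive recursion (memoised)."""

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == len(q) and j == len(t):
            return 0.0
        opts = []
        if i < len(q) and j < len(t):
            opts.append((MATCH if q[i] == t[j] else MISMATCH) + best(i + 1, j + 1))
        if i < len(q):
            opts.append(GAP + best(i + 1, j))
        if j < len(t):
            opts.append(GAP + best(i, j + 1))
        return max(opts)

    return best(0, 0)


class TestScoreAlign:
    def test_identical_sequences_score_one(self):
        assert score_align("ACGTACGTAC", "ACGTACGTAC").final_score == 1.0

    def test_one_mismatch_in_ten(self):
        a = score_align("ACGTACGTAC", "ACGTACGTAT")
        assert a.final_score == pytest.approx((9 * 1.0 - 0.2) / 10)

    def test_matches_enumeration_oracle_on_sampled_4mers(self):
        kmers = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
        rng = np.random.default_rng(0)
        for _ in range(300):
            q, t = rng.choice(kmers), rng.choice(kmers)
            got = score_align(q, t, mode="global").score
            assert got == pytest.approx(enumeration_oracle(q, t), abs=1e-9), (q, t)

    def test_degenerate_targets_match_both_pyrimidines(self):
        assert score_align("ACTG", "ACYG").final_score == 1.0
        assert score_align("ACCG", "ACYG").final_score == 1.0
        assert score_align("ACAG", "ACYG").final_score < 1.0

    def test_semi_global_read_inside_target_scores_one(self):
        target = "GGGG" + "ACGTACGTAC" + "TTTT"
        a = score_align("ACGTACGTAC", target, mode="semi-global")
        assert a.final_score == 1.0 and a.length == 10

    def test_non_dna_raises(self):
        with pytest.raises(ValueError):
            score_align("AC!T", "ACGT")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=12),
           st.text(alphabet="ACGT", min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_final_score_never_exceeds_one(self, q, t):
        assert score_align(q, t).final_score <= 1.0 + 1e-12


class TestSelectByPrimer:
    def _ref(self):
        return AmpliconRef("amp", "GTA" * 50, "GTAGTAGTAG", "TACTACTACT")

    def test_exact_prefixes_kept(self):
        ref = self._ref()
        kept, fate = select_by_primer([("GTAGTAGTAG" + "A" * 20, "TACTACTACT" + "C" * 20)], ref)
        assert fate["kept"] == 1 and len(kept) == 1

    def test_swapped_mates_reoriented(self):
        ref = self._ref()
        r1, r2 = "TACTACTACT" + "C" * 20, "GTAGTAGTAG" + "A" * 20
        kept, fate = select_by_primer([(r1, r2)], ref)
        assert fate["kept"] == 1
        assert kept[0] == (r2, r1)  # forward-primer mate first

    def test_random_prefixes_dropped(self):
        ref = self._ref()
        rng = np.random.default_rng(1)
        pairs = [
            ("".join(rng.choice(list("ACGT"), 30)), "".join(rng.choice(list("ACGT"), 30)))
            for _ in range(50)
        ]
        _, fate = select_by_primer(pairs, ref)
        assert fate["kept"] == 0

    def test_score_exactly_at_threshold_dropped(self):
        # 6-nt primer, one mismatch: (5 - 0.2)/6 = 0.8 exactly -> "higher
        # than 0.8" excludes it
        ref = AmpliconRef("amp", "AAATTT" + "G" * 50, "AAATTT", "CCCGGG")
        read1 = "AAATTA" + "G" * 20  # one mismatch against the forward primer
        read2 = "CCCGGG" + "G" * 20
        _, fate = select_by_primer([(read1, read2)], ref, prefix_len=6)
        assert fate["kept"] == 0


class TestConvertReference:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ACA", "ATA"), ("GCA", "GYA"), ("ACG", "AYG"), ("GCG", "GYG")],
    )
    def test_context_rules(self, seq, expected):
        assert convert_reference(seq).sequence == expected

    def test_context_classes_partition_cytosines(self, smf_ref):
        conv = convert_reference(smf_ref)
        seq = smf_ref.sequence
        for i, base in enumerate(seq):
            if base == "C":
                assert conv.context[i] in {"GCH", "HCG", "GCG", "HCH"}
            else:
                assert conv.context[i] == ""

    def test_gch_positions_are_gpc_not_followed_by_g(self, smf_ref):
        seq = smf_ref.sequence
        conv = convert_reference(smf_ref)
        expected = [
            i for i in range(1, len(seq))
            if seq[i] == "C" and seq[i - 1] == "G" and (i + 1 >= len(seq) or seq[i + 1] != "G")
        ]
        assert list(conv.gch_positions) == expected

    def test_g_positions_untouched(self):
        conv = convert_reference("GGCCGG")
        assert all(conv.sequence[i] == "G" for i, b in enumerate("GGCCGG") if b == "G")


class TestMapAndMerge:
    def test_error_free_pair_kept_and_reconstructed(self, smf_ref):
        conv = convert_reference(smf_ref)
        # an all-converted molecule (every convertible C read as T)
        molecule = conv.sequence.replace("Y", "T")
        pair = ((molecule[:250], np.full(250, 40)), (revcomp(molecule[-250:]), np.full(250, 40)))
        alns = map_full_length(pair, conv)
        assert alns is not None
        rebuilt = merge_pair(pair, alns, len(molecule))
        assert rebuilt == molecule

    def test_scrambled_pair_dropped(self, smf_ref):
        conv = convert_reference(smf_ref)
        rng = np.random.default_rng(2)
        junk = "".join(rng.choice(list("ACGT"), 250))
        assert map_full_length((junk, junk), conv) is None

    def test_overlap_conflict_resolved_by_quality(self):
        conv = convert_reference("GAAAAAAAAA")
        # mates fully overlap; mate 2 has a higher-quality discordant base
        m1 = ("GAAAAAAAAA", np.full(10, 10))
        m2_seq = revcomp("GAAAATAAAA")
        m2 = (m2_seq, np.full(10, 30)[::-1])
        alns = map_full_length((m1, m2), conv, threshold=0.5)
        merged = merge_pair((m1, m2), alns, 10)
        assert merged[5] == "T"

    def test_quality_tie_takes_mate1_base(self):
        conv = convert_reference("GAAAAAAAAA")
        m1 = ("GAAAAAAAAA", np.full(10, 20))
        m2 = (revcomp("GAAAATAAAA"), np.full(10, 20))
        alns = map_full_length((m1, m2), conv, threshold=0.5)
        assert merge_pair((m1, m2), alns, 10)[5] == "A"


class TestDedupDownsample:
    def test_copies_collapse_to_one(self):
        out = dedup_and_downsample({"s": ["ACGT"] * 10}, n=1)
        assert out["s"] == ["ACGT"]

    def test_min_unique_depth_helper(self):
        mols = {"a": ["A", "A", "C", "G"], "b": ["T", "T"]}
        assert min_unique_depth(mols) == 1

    def test_insufficient_unique_molecules_error_names_sample(self):
        with pytest.raises(ValueError, match="poor"):
            dedup_and_downsample({"poor": ["ACGT"] * 5, "rich": ["A", "C", "G"]}, n=2)

    def test_same_seed_same_selection(self):
        mols = {"s": [f"SEQ{i}" for i in range(100)]}
        a = dedup_and_downsample(mols, n=10, seed=3)
        b = dedup_and_downsample(mols, n=10, seed=3)
        c = dedup_and_downsample(mols, n=10, seed=4)
        assert a == b and a != c


class TestCallGch:
    def test_fully_accessible_molecule_all_zero(self):
        conv = convert_reference("AGCAGCAGCA")
        mol = "AGCAGCAGCA"  # every GCH cytosine still reads C
        assert (call_gch(mol, conv) == 0).all()

    def test_footprint_interval_reads_protected(self, smf_ref):
        conv = convert_reference(smf_ref)
        classes = [([(150, 260)], 1.0)]
        pairs, truth = synth.gen_smf_reads(
            smf_ref, classes, methylation_efficiency=1.0, conversion_rate=1.0,
            error_rate=0.0, dup_rate=0.0, n_per_sample=5, seed=23,
        )
        expected = truth.tables["class_calls"]["class_0"].to_numpy()
        for mol_seq in truth.tables["molecules"]["sequence"]:
            assert np.array_equal(call_gch(mol_seq, conv), expected)

    def test_gcg_positions_never_columns(self):
        conv = convert_reference("AGCGA")  # the only C is GCG context
        assert conv.gch_positions == ()


class TestClustering:
    def _two_prototypes(self, p=60):
        a = np.zeros(p)
        a[: p // 2] = 1.0
        return np.stack([a, 1.0 - a])

    def test_noiseless_complementary_prototypes_recovered(self):
        protos = self._two_prototypes()
        X, labels = synth.gen_protection_matrix(protos, n_per_cluster=20, flip_rate=0.0, seed=31)
        res = BinaryMatrixClustering(n_clusters=2, seed=0).fit(X)
        assert adjusted_rand_score(labels, res.labels_) == 1.0

    def test_ari_above_09_at_ten_percent_flips(self):
        protos = self._two_prototypes(p=80)  # 80 discriminating positions
        X, labels = synth.gen_protection_matrix(protos, n_per_cluster=150, flip_rate=0.1, seed=37)
        res = BinaryMatrixClustering(n_clusters=2, seed=0).fit(X)
        assert adjusted_rand_score(labels, res.labels_) >= 0.9

    def test_objective_non_increasing(self):
        protos = self._two_prototypes()
        X, _ = synth.gen_protection_matrix(protos, n_per_cluster=50, flip_rate=0.2,
                                           missing_rate=0.1, seed=41)
        res = BinaryMatrixClustering(n_clusters=3, n_restarts=1, seed=1).fit(X)
        diffs = np.diff(res.objective_path_)
        assert (diffs <= 1e-9).all()

    def test_missing_values_masked(self):
        protos = self._two_prototypes()
        X, labels = synth.gen_protection_matrix(protos, n_per_cluster=40, flip_rate=0.05,
                                                missing_rate=0.3, seed=43)
        res = BinaryMatrixClustering(n_clusters=2, seed=0).fit(X)
        assert adjusted_rand_score(labels, res.labels_) >= 0.9

    def test_k_larger_than_rows_raises(self):
        with pytest.raises(ValueError):
            BinaryMatrixClustering(n_clusters=5).fit(np.zeros((3, 4)))

    def test_deterministic_for_fixed_seed(self):
        X, _ = synth.gen_protection_matrix(self._two_prototypes(), 30, 0.2, seed=47)
        a = BinaryMatrixClustering(n_clusters=2, seed=7).fit(X)
        b = BinaryMatrixClustering(n_clusters=2, seed=7).fit(X)
        assert np.array_equal(a.labels_, b.labels_) and a.inertia_ == b.inertia_


class TestProtectionProfile:
    def _matrix(self, values, reps):
        return GchMatrix(values=np.asarray(values, float), positions=tuple(range(np.asarray(values).shape[1])),
                         replicates=tuple(reps))

    def _single_cluster(self, n):
        from nucaccess.smf import ClusterResult

        return ClusterResult(labels=np.zeros(n, int), prototypes=np.zeros((1, 1)),
                             objective=0.0, objective_path=np.zeros(1), k=1)

    def test_all_protected_column_is_100(self):
        mat = self._matrix([[1], [1], [1]], ["r1"] * 3)
        tab = protection_profile(self._single_cluster(3), mat)
        assert tab["pct_protection"].iloc[0] == 100.0

    def test_half_protected_column_is_50(self):
        mat = self._matrix([[1], [0], [1], [0]], ["r1"] * 4)
        tab = protection_profile(self._single_cluster(4), mat)
        assert tab["pct_protection"].iloc[0] == 50.0

    def test_sem_zero_for_identical_replicates(self):
        mat = self._matrix([[1], [0], [1], [0]], ["r1", "r1", "r2", "r2"])
        tab = protection_profile(self._single_cluster(4), mat)
        assert tab["sem"].iloc[0] == 0.0


class TestEndToEnd:
    def test_error_free_pipeline_recovers_truth_exactly(self, smf_ref):
        classes = [([(150, 260)], 0.5), ([], 0.5)]
        pairs, truth = synth.gen_smf_reads(
            smf_ref, classes, methylation_efficiency=1.0, conversion_rate=1.0,
            error_rate=0.0, dup_rate=0.0, n_per_sample=30,
            samples=("s1", "s2"), seed=29,
        )
        matrix, clusters, table, fate = run_pipeline(pairs, smf_ref, k=2, seed=29)
        for s in ("s1", "s2"):
            assert fate[s]["no_primer"] == 0 and fate[s]["dropped_mapping"] == 0
        truth_rows = {
            tuple(truth.tables["class_calls"][c]) for c in ("class_0", "class_1")
        }
        assert not np.isnan(matrix.values).any()
        for row in matrix.values:
            assert tuple(row) in truth_rows
        # the two classes land in distinct clusters
        assert len(set(map(tuple, clusters.prototypes))) == 2

    def test_duplicate_rate_halves_unique_molecules(self, smf_ref):
        classes = [([(150, 260)], 1.0)]
        pairs, truth = synth.gen_smf_reads(
            smf_ref, classes, methylation_efficiency=0.6, conversion_rate=1.0,
            error_rate=0.0, dup_rate=0.5, n_per_sample=400, seed=53,
        )
        dup_frac = truth.tables["molecules"]["is_duplicate"].mean()
        assert abs(dup_frac - 0.5) < 3 * np.sqrt(0.25 / 400)
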