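"""Encoder unit and property tests, including the naive-oracle checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrcascade import errors
from nrcascade.alphabets import (
    CGR12_ALPHABET,
    CTF_ALPHABET,
    STANDARD_AA,
    AlphabetMap,
    load_alphabet,
    write_alphabet,
)
from nrcascade.encode import (
    DEFAULT_CGR_CONFIG,
    FEATURE_DIMS,
    CGRPolygonConfig,
    SequenceEncoder,
    assign_segments,
    canonical_feature_set,
    cgr_features,
    cgr_trajectory,
    combine_features,
    compute_aac,
    compute_cgr,
    compute_ctf,
    encode_record,
    reduce_sequence,
    triad_index,
    triad_label,
)

protein = st.text(alphabet=STANDARD_AA, min_size=1, max_size=300)
protein3 = st.text(alphabet=STANDARD_AA, min_size=3, max_size=300)


def naive_ctf(seq: str) -> np.ndarray:
    """Independent oracle: materialize reduced 3-mers as strings, count in
    a dictionary, normalize by the window count."""
    reduced = "".join(str(CTF_ALPHABET.class_of[r]) for r in seq)
    counts: dict[str, int] = {}
    for j in range(len(seq) - 2):
        kmer = reduced[j : j + 3]
        counts[kmer] = counts.get(kmer, 0) + 1
    out = np.zeros(343)
    for kmer, n in counts.items():
        c1, c2, c3 = (int(ch) for ch in kmer)
        out[(c1 - 1) * 49 + (c2 - 1) * 7 + c3 - 1] = n / (len(seq) - 2)
    return out


class TestAlphabets:
    def test_ctf_partition_matches_published_classes(self):
        assert CTF_ALPHABET.groups == ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")
        assert [len(g) for g in CTF_ALPHABET.groups] == [3, 4, 4, 4, 2, 2, 1]

    def test_partition_must_cover_alphabet(self):
        with pytest.raises(errors.ConfigurationError, match="unassigned"):
            AlphabetMap("bad", ("AGV",))

    def test_partition_must_be_disjoint(self):
        with pytest.raises(errors.ConfigurationError, match="appears in"):
            AlphabetMap("bad", ("AGV", "AILFPYMTSHNQWRKDEC"))

    def test_alphabet_file_roundtrip(self, tmp_path):
        path = tmp_path / "alpha.txt"
        write_alphabet(CGR12_ALPHABET, path)
        loaded = load_alphabet(path, name="cgr12")
        assert loaded.groups == CGR12_ALPHABET.groups

    @pytest.mark.parametrize(
        "seq,expected",
        [("AGV", [1, 1, 1]), ("C", [7]), ("RKDE", [5, 5, 6, 6])],
    )
    def test_reduce_sequence(self, seq, expected):
        assert reduce_sequence(seq) == expected

    def test_reduce_names_position_and_residue(self):
        with pytest.raises(errors.SequenceDomainError, match="position 1"):
            CGR12_ALPHABET.reduce("A?C")


class TestAAC:
    @pytest.mark.parametrize(
        "seq,check",
        [
            ("AAAA", {"A": 1.0}),
            ("ACDEFGHIKLMNPQRSTVWY", {aa: 0.05 for aa in STANDARD_AA}),
            ("MKV", {"K": 1 / 3, "M": 1 / 3, "V": 1 / 3}),
        ],
    )
    def test_hand_counted_compositions(self, seq, check):
        vec = compute_aac(seq)
        for i, aa in enumerate(STANDARD_AA):
            assert vec.values[i] == pytest.approx(check.get(aa, 0.0))

    def test_empty_sequence_rejected(self):
        with pytest.raises(errors.SequenceDomainError):
            compute_aac("")


class TestTriadIndex:
    @pytest.mark.parametrize("triad,expected", [((1, 1, 1), 1), ((7, 7, 7), 343), ((1, 7, 6), 48)])
    def test_stated_formula(self, triad, expected):
        assert triad_index(*triad) == expected

    def test_bijective_over_343_types(self):
        seen = {
            triad_index(c1, c2, c3)
            for c1 in range(1, 8)
            for c2 in range(1, 8)
            for c3 in range(1, 8)
        }
        assert seen == set(range(1, 344))

    def test_out_of_range_rejected(self):
        with pytest.raises(errors.SequenceDomainError):
            triad_index(0, 1, 8)

    def test_labels_invert_indices(self):
        assert triad_label(triad_index(7, 5, 1)) == "C-RK-AGV"
        assert triad_label(1) == "AGV-AGV-AGV"


class TestCTF:
    def test_single_window(self):
        vec = compute_ctf("AAA")
        assert vec.values[triad_index(1, 1, 1) - 1] == 1.0
        assert vec.values.sum() == 1.0

    def test_two_window_hand_count(self):
        vec = compute_ctf("ACDA")  # windows ACD -> (1,7,6), CDA -> (7,6,1)
        assert vec.values[triad_index(1, 7, 6) - 1] == 0.5
        assert vec.values[triad_index(7, 6, 1) - 1] == 0.5
        assert np.count_nonzero(vec.values) == 2

    def test_short_sequence_states_minimum_length(self):
        with pytest.raises(errors.SequenceDomainError, match="3"):
            compute_ctf("MK")

    def test_oracle_equivalence_on_200_random_sequences(self, rng):
        from conftest import random_protein

        for _ in range(200):
            seq = random_protein(rng, int(rng.integers(3, 501)))
            np.testing.assert_allclose(
                compute_ctf(seq).values, naive_ctf(seq), atol=1e-12
            )


class TestCGR:
    def test_vertices_on_unit_circle_with_v1_east(self):
        verts = DEFAULT_CGR_CONFIG.vertices
        np.testing.assert_allclose(np.linalg.norm(verts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(verts[0], [1.0, 0.0], atol=1e-15)
        # vertex k at angle (k-1) * pi/6
        np.testing.assert_allclose(verts[3], [math.cos(math.pi / 2), math.sin(math.pi / 2)], atol=1e-12)

    def test_single_step_is_midpoint_of_origin_and_vertex(self):
        # 'A' is the sole member of vertex group 1 -> V1 = (1, 0)
        np.testing.assert_allclose(cgr_trajectory("A"), [[0.5, 0.0]])

    def test_two_steps_iterate_the_midpoint_map(self):
        np.testing.assert_allclose(cgr_trajectory("AA"), [[0.5, 0.0], [0.75, 0.0]])

    def test_boundary_point_goes_to_sector_one(self):
        vec = cgr_features(np.array([[0.5, 0.0]]))
        assert vec.values[0] == 1.0

    def test_boundary_rule_lower_index(self):
        # angle pi/2 lies between sectors 6 and 7: lower index wins
        assert assign_segments(np.array([[0.0, 0.7]]))[0] == 6
        # angle pi (negative x-axis) between 12 and 13 -> 12
        assert assign_segments(np.array([[-0.7, 0.0]]))[0] == 12

    def test_all_points_in_one_sector(self, rng):
        theta = rng.uniform(np.pi / 48, np.pi / 16, size=40)  # inside sector 1
        pts = 0.5 * np.column_stack((np.cos(theta), np.sin(theta)))
        vec = cgr_features(pts)
        assert vec.values[0] == 1.0 and vec.values.sum() == 1.0

    def test_trajectory_norms_strictly_below_one(self, rng):
        from conftest import random_protein

        for _ in range(25):
            pts = cgr_trajectory(random_protein(rng, int(rng.integers(1, 400))))
            assert (np.linalg.norm(pts, axis=1) < 1).all()

    def test_identical_input_gives_bit_identical_trajectories(self):
        seq = "MKVACDEFWYH" * 10
        a, b = cgr_trajectory(seq), cgr_trajectory(seq)
        assert (a == b).all()

    def test_config_requires_12_groups(self):
        with pytest.raises(errors.ConfigurationError, match="12"):
            CGRPolygonConfig(vertex_groups=CTF_ALPHABET)


class TestFeatureSets:
    @pytest.mark.parametrize(
        "name,dim",
        [
            ("aac", 20),
            ("cgr", 24),
            ("ctf", 343),
            ("aac+cgr", 44),
            ("aac+ctf", 363),
            ("ctf+cgr", 367),
            ("aac+cgr+ctf", 387),
        ],
    )
    def test_published_dimensionalities(self, name, dim):
        assert FEATURE_DIMS[name] == dim
        assert encode_record("MKVACDEFWYH", name).dimension == dim

    def test_user_order_is_canonicalized(self):
        assert canonical_feature_set("ctf+aac") == "aac+ctf"
        assert canonical_feature_set("CGR+CTF") == "ctf+cgr"
        with pytest.raises(errors.ConfigurationError):
            canonical_feature_set("aac+dipeptide")

    def test_single_block_combination_is_identity(self):
        block = compute_aac("MKV")
        assert combine_features([block]) is block

    def test_blocks_reordered_to_canonical_order(self):
        ctf, aac = compute_ctf("MKV"), compute_aac("MKV")
        combined = combine_features([ctf, aac])
        assert combined.feature_set == "aac+ctf"
        np.testing.assert_array_equal(combined.values[:20], aac.values)

    def test_concatenated_blocks_each_sum_to_one(self):
        vec = encode_record("MKVACDEFWYH", "aac+cgr+ctf")
        assert vec.values[:20].sum() == pytest.approx(1.0)
        assert vec.values[20:44].sum() == pytest.approx(1.0)
        assert vec.values[44:].sum() == pytest.approx(1.0)


class TestProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(protein3)
    def test_normalization_of_every_block(self, seq):
        assert compute_aac(seq).values.sum() == pytest.approx(1.0)
        assert compute_ctf(seq).values.sum() == pytest.approx(1.0)
        assert compute_cgr(seq).values.sum() == pytest.approx(1.0)
        assert (compute_ctf(seq).values >= 0).all()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(protein)
    def test_aac_and_cgr_cover_short_sequences(self, seq):
        assert compute_aac(seq).values.sum() == pytest.approx(1.0)
        assert compute_cgr(seq).values.sum() == pytest.approx(1.0)

    def test_permutation_changes_ctf_and_cgr_but_not_aac(self):
        a, b = "ACDEFGHIKL" * 3, "LKIHGFEDCA" * 3
        np.testing.assert_array_equal(compute_aac(a).values, compute_aac(b).values)
        assert not np.array_equal(compute_ctf(a).values, compute_ctf(b).values)
        assert not np.array_equal(compute_cgr(a).values, compute_cgr(b).values)

    def test_transformer_matches_function_api(self, rng):
        from conftest import random_protein

        seqs = [random_protein(rng, 50) for _ in range(5)]
        X = SequenceEncoder("aac+ctf").fit_transform(seqs)
        assert X.shape == (5, 363)
        np.testing.assert_array_equal(X[2], encode_record(seqs[2], "aac+ctf").values)
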