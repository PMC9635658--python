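import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtg import (
    FeatureTable,
    LabeledGeneSet,
    assemble_feature_table,
    compare_positive_vs_negative,
    expression_variability_features,
    feature_correlation_matrix,
    ppi_count_feature,
    read_string_edges,
    structural_features,
)
from eqtg.features import (
    ExpressionMatrix,
    GeneStructureRecord,
    PPINetwork,
    _normalize_edge_frame,
    read_domain_table,
    read_expression_matrix,
    read_gene_structures,
)

# ---------------------------------------------------------------------------
# STRING edge parsing
# ---------------------------------------------------------------------------


def _write_string(path, lines):
    path.write_text("protein1 protein2 combined_score\n" + "".join(l + "\n" for l in lines))


def test_undirected_duplicates_collapse(tmp_path):
    p = tmp_path / "ppi.tsv"
    _write_string(p, ["3702.AT1G01010 3702.AT1G01020 800",
                      "3702.AT1G01020 3702.AT1G01010 800"])
    net = read_string_edges(p, id_prefix_strip="3702.")
    assert net.n_edges == 1
    assert net.edges.iloc[0]["combined_score"] == 800
    assert set(net.edges.iloc[0][["protein_a", "protein_b"]]) == {"AT1G01010", "AT1G01020"}


def test_duplicate_edges_keep_max_score_and_self_loops_drop(tmp_path):
    p = tmp_path / "ppi.tsv"
    _write_string(p, ["a b 100", "b a 900", "c c 500"])
    net = read_string_edges(p)
    assert net.n_edges == 1
    assert net.edges.iloc[0]["combined_score"] == 900


def test_header_only_file_gives_empty_network(tmp_path):
    p = tmp_path / "ppi.tsv"
    _write_string(p, [])
    assert read_string_edges(p).n_edges == 0


@pytest.mark.parametrize(
    "line,message",
    [("a b", "3 whitespace-separated columns"),
     ("a b xyz", "non-integer score"),
     ("a b 1001", "outside")],
)
def test_malformed_lines_report_line_number(tmp_path, line, message):
    p = tmp_path / "ppi.tsv"
    _write_string(p, ["a b 500", line])
    with pytest.raises(ValueError, match=message) as err:
        read_string_edges(p)
    assert ":3:" in str(err.value)  # header is line 1


def test_random_edges_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    genes = [f"AT{i:03d}" for i in range(25)]
    written = set()
    lines = []
    for _ in range(100):
        i, j = rng.choice(25, size=2, replace=False)
        s = int(rng.integers(0, 1001))
        lines.append(f"{genes[i]} {genes[j]} {s}")
        written.add((min(genes[i], genes[j]), max(genes[i], genes[j]), s))
    p = tmp_path / "ppi.tsv"
    _write_string(p, lines)
    net = read_string_edges(p)
    # collapse the written multiset the same way: undirected max score
    best = {}
    for a, b, s in written:
        best[(a, b)] = max(best.get((a, b), -1), s)
    got = {(r.protein_a, r.protein_b): r.combined_score for r in net.edges.itertuples()}
    assert got == best


# ---------------------------------------------------------------------------
# PPI count feature
# ---------------------------------------------------------------------------


def test_score_700_boundary_is_inclusive():
    edges = pd.DataFrame(
        {"protein_a": ["g", "g", "g"], "protein_b": ["a", "b", "c"],
         "combined_score": [699, 700, 701]}
    )
    net = PPINetwork(_normalize_edge_frame(edges))
    counts = ppi_count_feature(net, ["g", "zzz"])
    assert counts.loc["g", "ppi count"] == 2  # 699 is "below 700", removed
    assert counts.loc["zzz", "ppi count"] == 0  # absent gene scores 0


def test_ppi_counts_match_brute_force_scan():
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(30)]
    rows = []
    for _ in range(200):
        i, j = rng.choice(30, size=2, replace=False)
        rows.append((genes[i], genes[j], int(rng.integers(0, 1001))))
    net = PPINetwork(_normalize_edge_frame(
        pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])
    ))
    for min_score in (0, 400, 700):
        counts = ppi_count_feature(net, genes, min_score=min_score)
        # brute force over the deduplicated edge list
        partners = {g: set() for g in genes}
        for r in net.edges.itertuples():
            if r.combined_score >= min_score:
                partners[r.protein_a].add(r.protein_b)
                partners[r.protein_b].add(r.protein_a)
        for g in genes:
            assert counts.loc[g, "ppi count"] == len(partners[g])


def test_ppi_counts_non_increasing_in_threshold():
    rng = np.random.default_rng(13)
    genes = [f"g{i}" for i in range(15)]
    rows = [(genes[a], genes[b], int(rng.integers(0, 1001)))
            for a, b in itertools.combinations(range(15), 2)]
    net = PPINetwork(_normalize_edge_frame(
        pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])
    ))
    prev = None
    for t in (0, 250, 500, 750, 1000):
        cur = ppi_count_feature(net, genes, min_score=t)["ppi count"]
        if prev is not None:
            assert (cur <= prev).all()
        prev = cur
    # at threshold 0 counts equal raw degree
    assert (ppi_count_feature(net, genes, 0)["ppi count"] == 14).all()


# ---------------------------------------------------------------------------
# Expression variability
# ---------------------------------------------------------------------------


def _expr(values, groups, classes=None):
    samples = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample_id"))
    if classes is not None:
        meta["class"] = classes
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples),
        meta,
    )


def test_constant_gene_has_zero_sd_across_tissues():
    expr = _expr(np.full((1, 9), 5.0), [f"t{i}" for i in range(9)])
    out = expression_variability_features(expr, "tissue")
    assert out.loc["g0", "SD exp. across tissues"] == 0.0


def test_accession_closed_form_mean_and_sample_sd():
    expr = _expr(np.array([[1.0, 2.0, 3.0]]), ["acc1", "acc2", "acc3"])
    out = expression_variability_features(expr, "accession")
    assert out.loc["g0", "avg exp. across accessions"] == pytest.approx(2.0)
    assert out.loc["g0", "SD exp. across accessions"] == pytest.approx(1.0)  # ddof=1


def test_replicates_averaged_within_group_first():
    # group means: t1 -> 2, t2 -> 6; SD over (2, 6) with ddof=1
    expr = _expr(np.array([[1.0, 3.0, 6.0]]), ["t1", "t1", "t2"])
    out = expression_variability_features(expr, "tissue")
    assert out.loc["g0", "SD exp. across tissues"] == pytest.approx(np.std([2.0, 6.0], ddof=1))


def test_random_matrix_matches_two_pass_recomputation():
    rng = np.random.default_rng(5)
    values = rng.gamma(2.0, 3.0, size=(50, 20))
    groups = [f"grp{i % 5}" for i in range(20)]
    classes = ["treatment" if i % 2 == 0 else "control" for i in range(20)]
    # condition grouping needs treatment/control to partition the groups
    groups_c = [f"e{i % 8}" for i in range(20)]
    classes_c = ["treatment" if int(g[1]) < 4 else "control" for g in groups_c]
    expr = _expr(values, groups)
    out = expression_variability_features(expr, "accession")
    # independent two-pass oracle
    frame = expr.values
    for g in range(50):
        by = {}
        for s, grp in zip(frame.columns, groups):
            by.setdefault(grp, []).append(frame.iloc[g][s])
        means = [np.mean(by[k]) for k in sorted(by)]
        assert out.iloc[g]["avg exp. across accessions"] == pytest.approx(np.mean(means))
        assert out.iloc[g]["SD exp. across accessions"] == pytest.approx(np.std(means, ddof=1))
    out_c = expression_variability_features(_expr(values, groups_c, classes_c), "condition")
    for g in range(0, 50, 7):
        for cls, avg_name in [("treatment", "avg exp. across treatments"),
                              ("control", "avg exp. across controls")]:
            by = {}
            for s, grp, c in zip(frame.columns, groups_c, classes_c):
                if c == cls:
                    by.setdefault(grp, []).append(frame.iloc[g][s])
            means = [np.mean(by[k]) for k in sorted(by)]
            assert out_c.iloc[g][avg_name] == pytest.approx(np.mean(means))


def test_translation_shifts_mean_not_sd():
    rng = np.random.default_rng(9)
    values = rng.gamma(2.0, 1.0, size=(5, 6))
    groups = ["a", "a", "b", "b", "c", "c"]
    base = expression_variability_features(_expr(values, groups), "accession")
    shifted = expression_variability_features(_expr(values + 3.0, groups), "accession")
    assert np.allclose(shifted["avg exp. across accessions"],
                       base["avg exp. across accessions"] + 3.0)
    assert np.allclose(shifted["SD exp. across accessions"],
                       base["SD exp. across accessions"])


def test_single_group_sd_is_validation_error():
    expr = _expr(np.ones((2, 3)), ["only", "only", "only"])
    with pytest.raises(ValueError, match=">= 2"):
        expression_variability_features(expr, "tissue")


def test_condition_grouping_requires_class_labels():
    expr = _expr(np.ones((2, 4)), ["e1", "e1", "e2", "e2"])
    with pytest.raises(ValueError, match="class"):
        expression_variability_features(expr, "condition")


# ---------------------------------------------------------------------------
# Structural features
# ---------------------------------------------------------------------------


def test_structural_definitions_forced_case():
    models = {"g1": GeneStructureRecord("g1", transcript_count=1, intron_count=4)}
    domains = pd.DataFrame({"gene_id": ["g1"] * 3, "domain_id": ["A", "A", "B"]})
    out = structural_features(models, domains, ["g1"])
    row = out.loc["g1"]
    assert row["introns"] == 4
    assert row["splice variants"] == 1
    assert row["total domains"] == 3
    assert row["unique domains"] == 2


def test_single_exon_gene_has_zero_introns(tmp_path):
    gff = tmp_path / "one.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsim\tgene\t100\t500\t.\t+\t.\tID=gA\n"
        "chr1\tsim\tmRNA\t100\t500\t.\t+\t.\tID=gA.1;Parent=gA\n"
        "chr1\tsim\texon\t100\t500\t.\t+\t.\tID=gA.1.e1;Parent=gA.1\n"
    )
    models = read_gene_structures(gff)
    assert models["gA"].intron_count == 0
    assert models["gA"].transcript_count == 1


def test_representative_transcript_is_longest_by_exon_sum(tmp_path):
    # gA.1: one 1000 bp exon; gA.2: three 100 bp exons -> gA.1 wins, introns 0
    gff = tmp_path / "two.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsim\tgene\t1\t2000\t.\t+\t.\tID=gA\n"
        "chr1\tsim\tmRNA\t1\t1000\t.\t+\t.\tID=gA.1;Parent=gA\n"
        "chr1\tsim\texon\t1\t1000\t.\t+\t.\tID=e1;Parent=gA.1\n"
        "chr1\tsim\tmRNA\t1\t2000\t.\t+\t.\tID=gA.2;Parent=gA\n"
        "chr1\tsim\texon\t1\t100\t.\t+\t.\tID=e2;Parent=gA.2\n"
        "chr1\tsim\texon\t201\t300\t.\t+\t.\tID=e3;Parent=gA.2\n"
        "chr1\tsim\texon\t401\t500\t.\t+\t.\tID=e4;Parent=gA.2\n"
    )
    models = read_gene_structures(gff)
    assert models["gA"].intron_count == 0
    assert models["gA"].transcript_count == 2


def test_simulated_annotation_matches_naive_recount(raw_inputs):
    models = read_gene_structures(raw_inputs.paths["gff"])
    domains = read_domain_table(raw_inputs.paths["domains"])
    out = structural_features(models, domains, list(raw_inputs.truth.index))
    for col in ["introns", "splice variants", "total domains", "unique domains"]:
        got = out[col].fillna(0.0)
        want = raw_inputs.truth[col].fillna(0.0)
        assert (got == want).all(), col
    assert (out["unique domains"].fillna(0) <= out["total domains"].fillna(0)).all()


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------


def test_assembly_imputes_and_masks_missing_cells():
    legacy = FeatureTable(pd.DataFrame(
        {"L1": [1.0, 2.0, 3.0], "L2": [4.0, 5.0, 6.0]}, index=["g1", "g2", "g3"]
    ))
    new = pd.DataFrame({"ppi count": [7.0, 8.0]}, index=["g1", "g2"])
    merged = assemble_feature_table(legacy, new)
    assert merged.values.shape == (3, 3)
    assert merged.values.loc["g3", "ppi count"] == 0.0
    assert bool(merged.missing.loc["g3", "ppi count"])
    assert not merged.missing.loc["g1"].any()


def test_assembly_is_idempotent_with_no_new_columns(small_sim):
    table = small_sim.table
    again = assemble_feature_table(table, [])
    pd.testing.assert_frame_equal(table.values, again.values)
    pd.testing.assert_frame_equal(table.missing, again.missing)


def test_every_output_cell_traces_to_its_source():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(12)]
    legacy = FeatureTable(pd.DataFrame(
        rng.standard_normal((12, 4)), index=genes, columns=["a", "b", "c", "d"]
    ))
    sub = sorted(rng.choice(genes, size=8, replace=False))
    new = pd.DataFrame(rng.standard_normal((8, 2)), index=sub, columns=["introns", "x_extra"])
    merged = assemble_feature_table(legacy, new)
    for g in genes:
        for col in ["a", "b", "c", "d"]:
            assert merged.values.loc[g, col] == legacy.values.loc[g, col]
        for col in ["introns", "x_extra"]:
            if g in sub:
                assert merged.values.loc[g, col] == new.loc[g, col]
            else:
                assert merged.missing.loc[g, col]


def test_assembly_rejects_name_clash_and_disjoint_genes():
    legacy = FeatureTable(pd.DataFrame({"a": [1.0]}, index=["g1"]))
    with pytest.raises(ValueError, match="clash"):
        assemble_feature_table(legacy, pd.DataFrame({"a": [2.0]}, index=["g1"]))
    with pytest.raises(ValueError, match="share no gene ids"):
        assemble_feature_table(legacy, pd.DataFrame({"b": [2.0]}, index=["gX"]))


# ---------------------------------------------------------------------------
# Correlations and class comparison
# ---------------------------------------------------------------------------


def test_correlation_identity_negation_and_zero_variance(toy_table):
    frame = pd.DataFrame(
        {"f": [1.0, 2.0, 3.0], "neg": [-1.0, -2.0, -3.0], "const": [5.0, 5.0, 5.0]},
        index=["g1", "g2", "g3"],
    )
    corr = feature_correlation_matrix(FeatureTable(frame))
    assert corr.loc["f", "f"] == 1.0
    assert corr.loc["f", "neg"] == pytest.approx(-1.0)
    # zero-variance feature: undefined, not 0
    assert np.isnan(corr.loc["f", "const"])
    assert corr.loc["const", "const"] == 1.0


def test_correlation_matches_definition_on_random_table():
    rng = np.random.default_rng(17)
    frame = pd.DataFrame(rng.standard_normal((40, 10)),
                         index=[f"g{i}" for i in range(40)],
                         columns=[f"f{i}" for i in range(10)])
    corr = feature_correlation_matrix(FeatureTable(frame))
    x = frame.to_numpy()
    for i in range(10):
        for j in range(10):
            xi = x[:, i] - x[:, i].mean()
            xj = x[:, j] - x[:, j].mean()
            want = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert abs(corr.iloc[i, j] - want) < 1e-10
    assert np.allclose(corr.to_numpy(), corr.to_numpy().T)


def test_identical_distributions_give_p_one():
    values = np.tile(np.arange(10.0), 2)
    frame = pd.DataFrame({"f": values}, index=[f"g{i}" for i in range(20)])
    labels = LabeledGeneSet([f"g{i}" for i in range(10)], [f"g{i}" for i in range(10, 20)])
    out = compare_positive_vs_negative(FeatureTable(frame), labels)
    assert out.loc["f", "p_value"] == pytest.approx(1.0)
    assert out.loc["f", "median_pos"] == out.loc["f", "median_neg"]


def test_complete_separation_gives_full_statistic():
    frame = pd.DataFrame(
        {"f": list(range(10, 20)) + list(range(10))},
        index=[f"g{i}" for i in range(20)], dtype=float,
    )
    labels = LabeledGeneSet([f"g{i}" for i in range(10)], [f"g{i}" for i in range(10, 20)])
    out = compare_positive_vs_negative(FeatureTable(frame), labels)
    assert out.loc["f", "statistic"] == 100  # n1 * n2


def test_small_sample_p_matches_exhaustive_permutation():
    rng = np.random.default_rng(23)
    for _ in range(20):
        n1, n2 = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        pos_vals = rng.standard_normal(n1)
        neg_vals = rng.standard_normal(n2)
        genes = [f"p{i}" for i in range(n1)] + [f"n{i}" for i in range(n2)]
        frame = pd.DataFrame({"f": np.concatenate([pos_vals, neg_vals])}, index=genes)
        labels = LabeledGeneSet(genes[:n1], genes[n1:])
        out = compare_positive_vs_negative(FeatureTable(frame), labels)
        # enumerate every assignment of ranks to the positive class
        ranks = stats.rankdata(frame["f"])
        mu = n1 * n2 / 2
        us = np.array([
            sum(ranks[list(comb)]) - n1 * (n1 + 1) / 2
            for comb in itertools.combinations(range(n1 + n2), n1)
        ])
        u_obs = out.loc["f", "statistic"]
        p_exact = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12))
        assert out.loc["f", "p_value"] == pytest.approx(p_exact, abs=1e-12)


def test_all_missing_class_reported_untestable():
    frame = pd.DataFrame({"f": [np.nan, np.nan, 1.0, 2.0]},
                         index=["p1", "p2", "n1", "n2"])
    labels = LabeledGeneSet(["p1", "p2"], ["n1", "n2"])
    out = compare_positive_vs_negative(FeatureTable(frame), labels)
    assert not out.loc["f", "testable"]
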