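"""DEG thresholding, module chi-square, term enrichment, metagene profiles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import sortscreen as ss
from sortscreen.errors import ConfigError, DegenerateTableError, FormatError


def pearson_chi2_oracle(obs: np.ndarray) -> float:
    """Direct Sigma (O - E)^2 / E, independent of the implementation path."""
    obs = np.asarray(obs, dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def modules_for_table(table: np.ndarray) -> tuple[set, pd.Series]:
    """Synthesize gene names + module labels realizing a 2x2 (module x DEG) table."""
    genes, labels, deg = [], [], set()
    i = 0
    for row, module in zip(table, ("PRC", "Myc")):
        for count, in_deg in zip(row, (True, False)):
            for _ in range(int(count)):
                g = f"g{i}"
                genes.append(g)
                labels.append(module)
                if in_deg:
                    deg.add(g)
                i += 1
    return deg, pd.Series(labels, index=genes)


class TestDegFilter:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame(
            {"gene": ["up", "down", "late", "weak", "flat"],
             "log2fc": [1.5, -2.0, 1.5, 0.5, 0.0],
             "p_value": [0.001, 0.005, 0.02, 0.001, 0.9]}
        )

    def test_threshold_semantics(self, table):
        up, down = ss.deg_filter(table)
        assert up == {"up"}          # "late" fails P, "weak" fails |lfc|
        assert down == {"down"}

    def test_up_and_down_disjoint(self, table):
        up, down = ss.deg_filter(table, lfc_abs_min=0.1, p_max=0.5)
        assert not up & down

    def test_missing_column_rejected(self):
        with pytest.raises(FormatError):
            ss.deg_filter(pd.DataFrame({"gene": ["g"], "log2fc": [1.0]}))


class TestModuleBias:
    def test_balanced_table_has_no_association(self):
        deg, modules = modules_for_table(np.array([[10, 10], [10, 10]]))
        r = ss.module_bias_test(deg, modules)
        assert r.chi2 == 0.0 and r.p_value == 1.0
        assert r.table.to_numpy().tolist() == [[10, 10], [10, 10]]

    def test_frozen_direct_formula_example(self):
        deg, modules = modules_for_table(np.array([[30, 10], [20, 40]]))
        r = ss.module_bias_test(deg, modules)
        assert r.chi2 == pytest.approx(16.666666667, rel=1e-9)
        assert r.p_value == pytest.approx(4.4557e-5, rel=1e-4)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_textbook_pearson_statistic(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 100, size=(2, 2))
        deg, modules = modules_for_table(table)
        r = ss.module_bias_test(deg, modules)
        assert r.chi2 == pytest.approx(pearson_chi2_oracle(table), rel=1e-10)
        assert r.p_value == pytest.approx(float(sps.chi2.sf(r.chi2, df=1)), rel=1e-10)

    def test_log10_p_survives_underflow(self):
        deg, modules = modules_for_table(np.array([[2000, 10], [10, 2000]]))
        r = ss.module_bias_test(deg, modules)
        assert r.p_value == 0.0       # below float64 underflow
        assert r.log10_p < -300       # but the magnitude is still reported

    def test_degenerate_table_rejected(self):
        # every module gene differentially expressed -> empty non-DEG column
        _, modules = modules_for_table(np.array([[5, 0], [5, 0]]))
        with pytest.raises(DegenerateTableError):
            ss.module_bias_test(set(modules.index), modules)

    def test_empty_module_rejected(self):
        _, modules = modules_for_table(np.array([[3, 3], [3, 3]]))
        with pytest.raises(ConfigError):
            ss.module_bias_test(set(), modules, "PRC", "NotAModule")


class TestTermFoldEnrichment:
    def test_fold_arithmetic(self):
        background = {f"g{i}" for i in range(1000)}
        candidates = {f"g{i}" for i in range(50)}
        terms = {f"g{i}": frozenset({"T"}) for i in list(range(5)) + list(range(900, 905))}
        out = ss.term_fold_enrichment(candidates, background, terms)
        row = out.iloc[0]
        assert row["term"] == "T" and row["fold"] == pytest.approx(10.0)
        assert (row["k"], row["n"], row["K"], row["N"]) == (5, 50, 10, 1000)
        assert row["p_value"] == pytest.approx(
            float(sps.hypergeom.sf(4, 1000, 10, 50)), rel=1e-12
        )

    def test_candidates_equal_background_gives_fold_one(self):
        genes = {f"g{i}" for i in range(20)}
        terms = {g: frozenset({"A"} if i % 2 else {"A", "B"}) for i, g in enumerate(sorted(genes))}
        out = ss.term_fold_enrichment(genes, genes, terms)
        assert np.allclose(out["fold"], 1.0)

    def test_ranking_matches_brute_force_sort(self):
        rng = np.random.default_rng(12)
        background = [f"g{i}" for i in range(300)]
        candidates = set(rng.choice(background, size=60, replace=False))
        terms = {
            g: frozenset(rng.choice([f"T{j}" for j in range(20)],
                                    size=rng.integers(0, 4), replace=False))
            for g in background
        }
        out = ss.term_fold_enrichment(candidates, set(background), terms)
        assert (out["k"] > 0).all()
        folds = out["fold"].to_numpy()
        assert (np.diff(folds) <= 1e-12).all()  # descending
        # fold recomputed independently per row
        for _, row in out.iterrows():
            assert row["fold"] == pytest.approx(
                (row["k"] / row["n"]) / (row["K"] / row["N"])
            )

    def test_fold_invariant_under_gene_relabeling(self):
        background = {f"g{i}" for i in range(100)}
        candidates = {f"g{i}" for i in range(30)}
        terms = {f"g{i}": frozenset({"T"}) for i in range(0, 100, 5)}
        relabel = {g: f"x_{g}" for g in background}
        out1 = ss.term_fold_enrichment(candidates, background, terms)
        out2 = ss.term_fold_enrichment(
            {relabel[g] for g in candidates},
            {relabel[g] for g in background},
            {relabel[g]: t for g, t in terms.items()},
        )
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_background_rejected(self):
        with pytest.raises(ConfigError):
            ss.term_fold_enrichment(set(), set(), {})


def write_bedgraph(path, segments):
    with open(path, "w") as fh:
        for chrom, start, end, value in segments:
            fh.write(f"{chrom}\t{start}\t{end}\t{value}\n")


def three_regions(strands=("+", "+", "-")):
    return pd.DataFrame(
        {"chrom": ["chr1"] * 3, "start": [100_000, 300_000, 600_000],
         "end": [104_000, 306_000, 604_000], "name": ["g1", "g2", "g3"],
         "score": [0, 0, 0], "strand": list(strands)}
    )


class TestMetagene:
    def test_identical_tracks_give_zero_everywhere(self, tmp_path):
        write_bedgraph(tmp_path / "a.bg", [("chr1", 0, 1_000_000, 2.0)])
        chip = ss.CoverageTrack.from_bedgraph(tmp_path / "a.bg")
        prof = ss.metagene_profile(chip, chip, three_regions())
        assert prof.n_regions == 3
        assert np.all(prof.log2_fe == 0.0)

    def test_uniform_scaling_of_one_track_changes_nothing(self, tmp_path):
        rng = np.random.default_rng(5)
        edges = np.linspace(0, 1_000_000, 201).astype(int)
        vals = rng.uniform(0.5, 4.0, size=200)
        write_bedgraph(tmp_path / "chip.bg",
                       [("chr1", a, b, v) for a, b, v in zip(edges[:-1], edges[1:], vals)])
        write_bedgraph(tmp_path / "chip2x.bg",
                       [("chr1", a, b, 2 * v) for a, b, v in zip(edges[:-1], edges[1:], vals)])
        write_bedgraph(tmp_path / "inp.bg", [("chr1", 0, 1_000_000, 1.0)])
        inp = ss.CoverageTrack.from_bedgraph(tmp_path / "inp.bg")
        p1 = ss.metagene_profile(ss.CoverageTrack.from_bedgraph(tmp_path / "chip.bg"),
                                 inp, three_regions())
        p2 = ss.metagene_profile(ss.CoverageTrack.from_bedgraph(tmp_path / "chip2x.bg"),
                                 inp, three_regions())
        assert np.allclose(p1.log2_fe, p2.log2_fe)

    def test_rectangular_body_enrichment_recovered(self, tmp_path):
        regions = three_regions(strands=("+", "+", "+"))
        chip_segs, pos = [], 0
        for _, r in regions.iterrows():
            chip_segs += [("chr1", pos, r["start"], 1.0),
                          ("chr1", r["start"], r["end"], 4.0)]
            pos = r["end"]
        chip_segs.append(("chr1", pos, 1_000_000, 1.0))
        write_bedgraph(tmp_path / "chip.bg", chip_segs)
        write_bedgraph(tmp_path / "inp.bg", [("chr1", 0, 1_000_000, 1.0)])
        prof = ss.metagene_profile(
            ss.CoverageTrack.from_bedgraph(tmp_path / "chip.bg"),
            ss.CoverageTrack.from_bedgraph(tmp_path / "inp.bg"),
            regions, pseudocount=1e-9,
        )
        frame = prof.to_frame()
        body = frame.loc[frame["zone"] == "body", "log2_fe"]
        flank = frame.loc[frame["zone"] != "body", "log2_fe"]
        assert np.allclose(body, 2.0, atol=0.1)
        assert np.allclose(flank, 0.0, atol=0.1)

    def test_minus_strand_profile_is_reversed(self, tmp_path):
        # enrichment over the upstream flank only: must land in the leading
        # bins for both strands after orientation
        write_bedgraph(tmp_path / "inp.bg", [("chr1", 0, 1_000_000, 1.0)])
        plus = pd.DataFrame({"chrom": ["chr1"], "start": [500_000], "end": [504_000],
                             "name": ["g"], "score": [0], "strand": ["+"]})
        minus = plus.assign(strand="-")
        # upstream for '+' is [498000, 500000); for '-' it is [504000, 506000)
        write_bedgraph(tmp_path / "chip_p.bg",
                       [("chr1", 0, 498_000, 1.0), ("chr1", 498_000, 500_000, 5.0),
                        ("chr1", 500_000, 1_000_000, 1.0)])
        write_bedgraph(tmp_path / "chip_m.bg",
                       [("chr1", 0, 504_000, 1.0), ("chr1", 504_000, 506_000, 5.0),
                        ("chr1", 506_000, 1_000_000, 1.0)])
        inp = ss.CoverageTrack.from_bedgraph(tmp_path / "inp.bg")
        pp = ss.metagene_profile(ss.CoverageTrack.from_bedgraph(tmp_path / "chip_p.bg"), inp, plus)
        pm = ss.metagene_profile(ss.CoverageTrack.from_bedgraph(tmp_path / "chip_m.bg"), inp, minus)
        assert np.allclose(pp.log2_fe, pm.log2_fe, atol=1e-9)
        assert pp.log2_fe[:50].mean() > 1.5  # enrichment sits in the 5' flank bins

    def test_out_of_bounds_region_skipped_with_warning(self, tmp_path):
        write_bedgraph(tmp_path / "a.bg", [("chr1", 0, 200_000, 1.0)])
        track = ss.CoverageTrack.from_bedgraph(tmp_path / "a.bg")
        regions = three_regions()  # g2/g3 extend beyond 200 kb
        with pytest.warns(UserWarning, match="skipped"):
            prof = ss.metagene_profile(track, track, regions)
        assert prof.n_regions == 1

    def test_all_regions_skipped_is_an_error(self, tmp_path):
        write_bedgraph(tmp_path / "a.bg", [("chr1", 0, 1000, 1.0)])
        track = ss.CoverageTrack.from_bedgraph(tmp_path / "a.bg")
        with pytest.raises(ConfigError), pytest.warns(UserWarning):
            ss.metagene_profile(track, track, three_regions())

    def test_bed_reader_validates(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t10\t5\tg\t0\t+\n")
        with pytest.raises(FormatError):
            ss.read_bed(bad)
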