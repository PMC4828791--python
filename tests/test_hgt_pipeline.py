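import json

import pytest
from click.testing import CliRunner

from hgtscreen.cli import main as cli_main
from hgtscreen.hgt import (
    TaxonomyMap,
    build_constraints,
    hgt_model_test,
    hgt_verdict,
    read_constraint_spec,
    taxonomy_constraint,
)
from hgtscreen.pipeline import PipelineConfig, run_hgt_pipeline
from hgtscreen.search import SearchConfig
from hgtscreen.simulate import SimConfig, make_hgt_benchmark
from hgtscreen.substmodels import SubstitutionModel

SMALL = SimConfig(
    n_taxa=8, n_sites=150, donor_clade_size=2, hgt=True, seed=19,
    model=SubstitutionModel("LG", gamma_shape=1.0),
)
MODEL = SubstitutionModel("LG", gamma_shape=1.0)


class TestTaxonomyAndConstraints:
    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("s1\tEukaryota\tNematoda\ns2\tBacteria\tActinomycetes\n")
        tm = TaxonomyMap.read_tsv(p)
        assert tm.lineages["s1"] == ("Eukaryota", "Nematoda")
        assert tm.ids_with_label("Bacteria") == {"s2"}

    def test_merge_expression_builds_union_group(self):
        tm = TaxonomyMap(
            {"e1": ("Euk",), "e2": ("Euk",), "a1": ("Arch",), "b1": ("Bact",)}
        )
        (cs,) = build_constraints(tm, ["Euk + Arch"])
        assert cs.groups["Euk + Arch"] == {"e1", "e2", "a1"}

    def test_unknown_label_named_in_error(self):
        tm = TaxonomyMap({"x": ("A",)})
        with pytest.raises(ValueError, match="Insects"):
            build_constraints(tm, ["A + Insects"])

    def test_empty_spec_gives_empty_list(self):
        assert build_constraints(TaxonomyMap({"x": ("A",)}), []) == []

    def test_taxonomy_constraint_uses_top_level_labels(self, hgt_benchmark):
        cs = taxonomy_constraint(
            hgt_benchmark.taxonomy, hgt_benchmark.alignment.ids
        )
        assert set(cs.groups) == {
            "Nematoda", "Actinobacteria", "Fungi", "Proteobacteria"
        }

    def test_constraint_file_formats(self, tmp_path):
        p = tmp_path / "spec.txt"
        p.write_text("cladeA\ta,b,c\ncladeB\td,e\nEuk + Arch\n")
        entries = read_constraint_spec(p)
        # tab lines merge into one vertical-descent model; labels stay separate
        assert entries[0].groups == {
            "cladeA": {"a", "b", "c"},
            "cladeB": {"d", "e"},
        }
        assert entries[1] == "Euk + Arch"


class TestHgtModelTest:
    def test_transfer_dataset_gets_very_strong_delta(self):
        b = make_hgt_benchmark(SMALL)
        comp = hgt_model_test(
            b.alignment, MODEL, [b.vertical_constraint], SearchConfig(seed=1, tol=1e-3)
        )
        assert comp.rows[0].delta_bic >= 5.0
        assert hgt_verdict(comp) == "HGT supported"

    def test_vertical_dataset_stays_below_threshold(self):
        b = make_hgt_benchmark(
            SimConfig(
                n_taxa=8, n_sites=150, donor_clade_size=2, hgt=False, seed=19,
                model=MODEL,
            )
        )
        comp = hgt_model_test(
            b.alignment, MODEL, [b.vertical_constraint], SearchConfig(seed=1, tol=1e-3)
        )
        assert comp.rows[0].delta_bic < 5.0
        assert hgt_verdict(comp) == "HGT not supported"

    def test_repeat_run_is_bit_identical(self):
        b = make_hgt_benchmark(SMALL)
        kw = dict(cfg=SearchConfig(seed=4, tol=1e-3))
        c1 = hgt_model_test(b.alignment, MODEL, [b.vertical_constraint], **kw)
        c2 = hgt_model_test(b.alignment, MODEL, [b.vertical_constraint], **kw)
        assert c1.rows[0].delta_bic == c2.rows[0].delta_bic
        assert c1.reference.lnL == c2.reference.lnL

    def test_requires_a_constraint_set(self):
        b = make_hgt_benchmark(SMALL)
        with pytest.raises(ValueError):
            hgt_model_test(b.alignment, MODEL, [], SearchConfig())


def _write_bundle(tmp_path, seed=19, hgt=True):
    runner = CliRunner()
    out = tmp_path / ("hgt" if hgt else "vert")
    res = runner.invoke(
        cli_main,
        ["simulate", "--preset", "hgt" if hgt else "vertical", "--taxa", "8",
         "--sites", "150", "--seed", str(seed), "--out", str(out)],
    )
    assert res.exit_code == 0, res.output
    return out


class TestPipeline:
    def test_end_to_end_on_transfer_bundle(self, tmp_path):
        bundle = _write_bundle(tmp_path)
        cfg = PipelineConfig(
            alignment=str(bundle / "alignment.fasta"),
            taxonomy=str(bundle / "taxonomy.tsv"),
            constraints=str(bundle / "constraints.txt"),
            cds=str(bundle / "focal_cds.fasta"),
            recipient_cds=str(bundle / "recipient_cds.fasta"),
            donor_cds=str(bundle / "donor_cds.fasta"),
            out_dir=str(tmp_path / "out"),
            candidate_models=("LG+G",),
            n_bootstrap=5,
            seed=2,
        )
        summary = run_hgt_pipeline(cfg)
        assert summary["hgt_verdict"] == "HGT supported"
        assert summary["model"] == "LG + G"
        assert (tmp_path / "out" / "ml_tree.nwk").exists()
        assert (tmp_path / "out" / "comparison.tsv").exists()
        comp_rows = summary["composition"]
        assert comp_rows and "gc_class" in comp_rows[0]

    def test_rerun_is_byte_identical(self, tmp_path):
        bundle = _write_bundle(tmp_path)
        outs = []
        for d in ("o1", "o2"):
            cfg = PipelineConfig(
                alignment=str(bundle / "alignment.fasta"),
                taxonomy=str(bundle / "taxonomy.tsv"),
                constraints=str(bundle / "constraints.txt"),
                out_dir=str(tmp_path / d),
                candidate_models=("LG+G",),
                n_bootstrap=3,
                seed=7,
            )
            run_hgt_pipeline(cfg)
            outs.append(
                [
                    (tmp_path / d / f).read_bytes()
                    for f in ("summary.json", "comparison.tsv", "ml_tree.nwk")
                ]
            )
        assert outs[0] == outs[1]

    def test_summary_carries_reproducibility_fields(self, tmp_path):
        bundle = _write_bundle(tmp_path)
        cfg = PipelineConfig(
            alignment=str(bundle / "alignment.fasta"),
            taxonomy=str(bundle / "taxonomy.tsv"),
            out_dir=str(tmp_path / "o3"),
            candidate_models=("LG", "LG+G"),
            n_bootstrap=3,
            seed=11,
        )
        summary = run_hgt_pipeline(cfg)
        saved = json.loads((tmp_path / "o3" / "summary.json").read_text())
        for key in ("version", "seed", "model", "K", "n_sites"):
            assert key in saved
        assert saved["seed"] == 11
        assert summary["n_sites"] == 150

    def test_toml_config_round_trip(self, tmp_path):
        bundle = _write_bundle(tmp_path)
        toml = tmp_path / "run.toml"
        toml.write_text(
            f'alignment = "{bundle / "alignment.fasta"}"\n'
            f'taxonomy = "{bundle / "taxonomy.tsv"}"\n'
            f'out_dir = "{tmp_path / "o4"}"\n'
            'candidate_models = ["LG+G"]\n'
            "n_bootstrap = 3\nseed = 5\n"
        )
        cfg = PipelineConfig.from_toml(toml)
        assert cfg.seed == 5 and cfg.candidate_models == ("LG+G",)


class TestCli:
    def test_screen_command(self, tmp_path):
        hits = tmp_path / "hits.tsv"
        hits.write_text(
            "q\tsub1\t90\t120\t3\t0\t1\t120\t5\t124\t1e-20\t200\n"
            "q\tsub2\t90\t120\t3\t0\t1\t120\t5\t124\t0.01\t50\n"
        )
        tax = tmp_path / "tax.tsv"
        tax.write_text("sub1\tBacteria\nsub2\tBacteria\n")
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["screen", "--hits", str(hits), "--taxonomy", str(tax),
             "--out-prefix", str(tmp_path / "scr")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "scr.selected.txt").read_text().strip() == "sub1"

    def test_hgt_test_command(self, tmp_path):
        bundle = _write_bundle(tmp_path)
        out = tmp_path / "table.tsv"
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["test", "--aln", str(bundle / "alignment.fasta"),
             "--taxonomy", str(bundle / "taxonomy.tsv"),
             "--constraints", str(bundle / "constraints.txt"),
             "--model", "LG+G", "--seed", "3", "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        text = out.read_text()
        assert text.startswith("Rank\tConstraint")
        assert "Unconstrained" in text
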