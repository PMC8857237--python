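"""Planted-truth recovery, generator calibration, and determinism."""

import hashlib
import json
import math

import numpy as np
import pytest

from linafunnel.assay import spectrum_from_assay
from linafunnel.errors import InputError
from linafunnel.funnel import call_bgc_core, expressed_genes, unique_to_clade
from linafunnel.screen import annotate_all, filter_artifacts, recurrently_hit_genes
from linafunnel.simulate import (
    AssayProtocol,
    GeneratorConfig,
    gen_bgc_genome,
    gen_droplet_assay,
    gen_expression,
    gen_funnel_fixture,
    gen_mutants,
    gen_pangenome,
    spectrum_truth,
)

TARGETS = ["VT1065", "BAM582"]


class TestConfig:
    def test_identical_targets_rejected(self):
        with pytest.raises(InputError):
            GeneratorConfig(seed=1, target_ids=("A", "A"))

    def test_zero_forcing_bounded_by_unique(self):
        with pytest.raises(InputError):
            GeneratorConfig(seed=1, n_unique=2, n_zero_expression=3)

    def test_causal_split_must_cover_lost_strains(self):
        with pytest.raises(InputError):
            GeneratorConfig(seed=1, n_lost=6, causal_split=(5, 2))

    def test_unknown_yaml_keys_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("seed: 1\nwhat_is_this: 5\n")
        with pytest.raises(InputError, match="unknown config keys"):
            GeneratorConfig.from_yaml(p)


class TestPangenome:
    def test_planted_unique_recovered_exactly(self, small_bundle):
        truth = set(small_bundle.manifest["planted_truth"]["unique_reference_tags"])
        got = unique_to_clade(small_bundle.matrix, TARGETS)
        assert got == truth

    def test_no_unique_clusters_when_none_planted(self):
        cfg = GeneratorConfig(seed=9, n_unique=0, n_zero_expression=0)
        rng = np.random.default_rng(9)
        matrix, _, truth = gen_pangenome(cfg, rng)
        assert unique_to_clade(matrix, TARGETS) == set()
        assert truth["unique_reference_tags"] == []

    def test_recovery_invariant_to_genome_order(self, small_bundle):
        from linafunnel.funnel import PresenceAbsenceMatrix

        occ = small_bundle.matrix.occupancy
        shuffled = PresenceAbsenceMatrix(occ[list(reversed(occ.columns))])
        assert unique_to_clade(shuffled, TARGETS) == unique_to_clade(
            small_bundle.matrix, TARGETS
        )


class TestExpression:
    def test_forced_zero_genes_have_zero_tpm(self, small_bundle):
        zeros = small_bundle.manifest["planted_truth"]["zero_expression_genes"]
        table = small_bundle.expression
        assert len(zeros) == small_bundle.config.n_zero_expression
        assert all(table.frame.at[g, "tpm"] == 0 for g in zeros)
        unique = set(small_bundle.manifest["planted_truth"]["unique_reference_tags"])
        assert unique & expressed_genes(table) == unique - set(zeros)

    def test_tpm_sums_to_a_million(self, small_bundle):
        assert small_bundle.expression.frame["tpm"].sum() == pytest.approx(1e6, rel=1e-6)

    def test_negative_binomial_zero_mass_is_small(self):
        # P(count=0) under the default model, from the closed form
        cfg = GeneratorConfig(seed=1)
        r, mu = cfg.nb_dispersion, cfg.nb_mean
        p0 = (r / (r + mu)) ** r
        assert p0 < 1e-3

    def test_over_forcing_rejected(self):
        cfg = GeneratorConfig(seed=1, n_unique=80, n_zero_expression=3)
        rng = np.random.default_rng(1)
        with pytest.raises(InputError):
            gen_expression(cfg, ["a", "b"], ["a", "b", "missing"], rng)


class TestBgcGenome:
    def test_template_yields_one_region_five_core_genes(self):
        cfg = GeneratorConfig(seed=13)
        bgc = gen_bgc_genome(cfg, np.random.default_rng(13))
        regions, core = call_bgc_core(bgc.annotations)
        assert core == set(bgc.cluster_gene_ids)
        assert len(regions) == 1

    def test_extra_clusters_add_core_genes(self):
        cfg = GeneratorConfig(seed=13, n_extra_core_clusters=1)
        bgc = gen_bgc_genome(cfg, np.random.default_rng(13))
        regions, core = call_bgc_core(bgc.annotations)
        assert len(regions) == 2
        assert core == set(bgc.cluster_gene_ids) | set(bgc.extra_core_gene_ids)

    def test_stripping_signature_domains_leaves_nothing(self):
        cfg = GeneratorConfig(seed=13)
        bgc = gen_bgc_genome(cfg, np.random.default_rng(13))
        from linafunnel.funnel import DomainAnnotation

        stripped = [
            DomainAnnotation(a.gene_id, (), a.contig, a.start, a.end, a.strand)
            for a in bgc.annotations
        ]
        regions, core = call_bgc_core(stripped)
        assert regions == [] and core == set()

    def test_cds_lengths_are_codon_multiples(self):
        bgc = gen_bgc_genome(GeneratorConfig(seed=14), np.random.default_rng(14))
        assert all(g.length % 3 == 0 for g in bgc.gene_models)
        # flags derived as intended
        assert all(
            by_id.is_insertion_sequence
            for by_id in bgc.gene_models
            if by_id.gene_id in bgc.is_gene_ids
        )


class TestMutants:
    def test_wild_type_strains_never_hit_causal_genes(self, small_bundle):
        causal = set(small_bundle.manifest["planted_truth"]["causal_gene_ids"])
        gm, genome = small_bundle.bgc.gene_models, small_bundle.bgc.genome
        wt = {m.strain_id for m in small_bundle.phenotypes if m.phenotype == "wild_type"}
        for strain in wt:
            anns = annotate_all(small_bundle.variants[strain], gm, genome)
            assert not {v.gene_id for v in anns} & causal

    def test_artifact_filter_spares_causal_hits(self, small_bundle):
        gm, genome = small_bundle.bgc.gene_models, small_bundle.bgc.genome
        allv = [v for s in sorted(small_bundle.variants) for v in small_bundle.variants[s]]
        kept, log = filter_artifacts(annotate_all(allv, gm, genome), gm)
        truth = small_bundle.manifest["planted_truth"]
        kept_keys = {(v.strain_id, v.pos) for v in kept}
        for strain, hit in truth["causal_hits"].items():
            for pos in hit["positions"]:
                assert (strain, pos) in kept_keys
        # every planted artifact carrier was removed
        removed = {(e["strain_id"], e["pos"]) for e in log}
        for site in truth["artifact_sites"]:
            for strain in site["strains"]:
                assert (strain, site["pos"]) in removed

    def test_recurrence_recovers_exactly_the_causal_genes(self, small_bundle):
        gm, genome = small_bundle.bgc.gene_models, small_bundle.bgc.genome
        allv = [v for s in sorted(small_bundle.variants) for v in small_bundle.variants[s]]
        kept, _ = filter_artifacts(annotate_all(allv, gm, genome), gm)
        hits = recurrently_hit_genes(kept, small_bundle.phenotypes, min_strains=2)
        split = small_bundle.config.causal_split
        assert [(h.gene_id, h.n_strains) for h in hits] == [
            (small_bundle.bgc.pks_gene_id, split[0]),
            (small_bundle.bgc.nrps_gene_id, split[1]),
        ]

    def test_background_load_matches_poisson_mean(self):
        """Mean candidate-effect load over 1000 strains is ~4 (3 SE band)."""
        cfg = GeneratorConfig(
            seed=7, n_lost=0, n_reduced=0, n_wt=1000, n_artifact_variants=0
        )
        rng = np.random.default_rng(7)
        bgc = gen_bgc_genome(cfg, rng)
        variants, _, truth = gen_mutants(cfg, bgc.genome, bgc.gene_models, rng)
        counts = np.array([len(variants[s]) for s in variants])
        assert (counts == np.array(list(truth["background_counts"].values()))).all()
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - cfg.mutation_lambda) <= 3 * se

    def test_missing_causal_gene_rejected(self):
        cfg = GeneratorConfig(seed=15)
        rng = np.random.default_rng(15)
        bgc = gen_bgc_genome(cfg, rng)
        with pytest.raises(InputError, match="causal"):
            gen_mutants(cfg, bgc.genome, bgc.gene_models, rng,
                        causal_gene_ids=("nope1", "nope2"))


class TestDropletAssay:
    def test_zero_spectrum_never_freezes(self):
        cfg = GeneratorConfig(seed=16)
        temps = cfg.protocol.temperatures()
        series, control = gen_droplet_assay(
            cfg, np.zeros(len(temps)), np.random.default_rng(16)
        )
        assert all(f == 0 for s in series for f in s.frozen_counts)
        assert all(f == 0 for s in control for f in s.frozen_counts)

    def test_non_monotone_spectrum_rejected(self):
        cfg = GeneratorConfig(seed=16)
        k = np.linspace(0, 1e-6, len(cfg.protocol.temperatures()))[::-1].copy()
        with pytest.raises(InputError, match="non-decreasing"):
            gen_droplet_assay(cfg, k, np.random.default_rng(16))

    def test_unfrozen_fraction_follows_poisson_void_probability(self):
        """P(droplet unfrozen at theta) -> exp(-K * A), 3-sigma binomial band."""
        cfg = GeneratorConfig(
            seed=17,
            protocol=AssayProtocol(n_drops=3000, n_dilutions=1, n_replicates=1,
                                   start_cfu_per_ml=1e5),
        )
        temps = cfg.protocol.temperatures()
        k = spectrum_truth(cfg.spectrum, temps)
        series, _ = gen_droplet_assay(cfg, k, np.random.default_rng(17))
        s = series[0]
        for i in range(len(temps)):
            p_unfrozen = math.exp(-k[i] * s.cfu_per_drop)
            got = (s.n_drops - s.frozen_counts[i]) / s.n_drops
            sigma = math.sqrt(p_unfrozen * (1 - p_unfrozen) / s.n_drops)
            assert abs(got - p_unfrozen) <= 3 * sigma + 1e-12

    def test_estimator_round_trip(self):
        cfg = GeneratorConfig(seed=18, protocol=AssayProtocol(n_drops=300))
        temps = cfg.protocol.temperatures()
        k_true = spectrum_truth(cfg.spectrum, temps)
        series, _ = gen_droplet_assay(cfg, k_true, np.random.default_rng(18))
        sp = spectrum_from_assay(series)
        informative = [
            i for i in range(len(temps))
            if k_true[i] > 0 and not sp.censored[i] and sp.n_series_used[i] > 0
        ]
        assert informative
        for i in informative:
            assert sp.k_per_cfu[i] == pytest.approx(k_true[i], rel=0.5)


class TestDeterminism:
    @staticmethod
    def _bundle_digest(tmpdir, seed):
        from linafunnel.io import write_bundle

        cfg = GeneratorConfig(seed=seed, n_wt=1)
        bundle = gen_funnel_fixture(cfg)
        out = tmpdir / f"b{seed}"
        write_bundle(bundle, out)
        h = hashlib.sha256()
        for f in sorted(out.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
        return h.hexdigest()

    def test_same_seed_byte_identical_files(self, tmp_path):
        d1 = self._bundle_digest(tmp_path / "run1", 21)
        d2 = self._bundle_digest(tmp_path / "run2", 21)
        assert d1 == d2

    def test_different_seed_differs(self, tmp_path):
        d1 = self._bundle_digest(tmp_path / "run1", 21)
        d3 = self._bundle_digest(tmp_path / "run3", 22)
        assert d1 != d3

    def test_manifest_is_json_serializable(self, small_bundle):
        blob = json.dumps(small_bundle.manifest, sort_keys=True)
        assert "planted_truth" in json.loads(blob)
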