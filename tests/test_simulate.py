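"""Synthetic cohort generator: determinism, margins, ground-truth recovery."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest

from sibcnv import CohortConfig, assign_outcome_label, generate_cohort
from sibcnv.io import read_pedigree, read_psychometrics, read_cnv_calls
from sibcnv.simulate import (
    ConfigError,
    PlantSpec,
    generate_algorithm_calls,
    generate_control_cohort,
)
from sibcnv.genomic import GenomicInterval, reciprocal_overlap


def _tree_digest(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


class TestConfig:
    def test_defaults_are_consistent(self):
        cfg = CohortConfig()
        cfg.validate()
        assert cfg.n_siblings == 288
        assert cfg.n_typical == 131

    def test_inconsistent_family_sizes_rejected(self):
        cfg = dataclasses.replace(CohortConfig(), family_sizes=((1, 100),))
        with pytest.raises(ConfigError, match="family"):
            cfg.validate()

    def test_carrier_plan_must_fit_margins(self):
        plan = tuple(
            PlantSpec("sibling", "typical", "candidate_gene", "CAND_A",
                      "deletion", "maternal", "VUS")
            for _ in range(140)
        )
        cfg = dataclasses.replace(CohortConfig(), sibling_plants=plan)
        with pytest.raises(ConfigError, match="margin"):
            cfg.validate()

    def test_excessive_jitter_rejected(self):
        cfg = dataclasses.replace(CohortConfig(), jitter_bp=30_000)
        with pytest.raises(ConfigError, match="jitter"):
            cfg.validate()


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        a = generate_cohort(CohortConfig(), tmp_path / "a", seed=11)
        b = generate_cohort(CohortConfig(), tmp_path / "b", seed=11)
        assert _tree_digest(a.root) == _tree_digest(b.root)

    def test_different_seed_differs(self, tmp_path, bundle):
        other = generate_cohort(CohortConfig(), tmp_path / "c", seed=2)
        assert _tree_digest(other.root) != _tree_digest(bundle.root)


class TestCohortComposition:
    def test_pedigree_structure(self, bundle):
        ped = read_pedigree(bundle.pedigree)
        roles = {}
        for r in ped:
            roles[r.role] = roles.get(r.role, 0) + 1
        assert roles["proband"] == 253
        assert roles["sibling"] == 288
        assert roles["mother"] == roles["father"] == 253

    def test_phenotype_margins_exact(self, bundle):
        labels = [
            assign_outcome_label(rec, "BSRC").label
            for rec in read_psychometrics(bundle.psychometrics)
        ]
        assert labels.count("ASD") == 103
        assert labels.count("atypical") == 54
        assert labels.count("typical") == 131


class TestCallGeneration:
    def test_planted_cnv_supported_by_concordant_callers(self):
        cfg = CohortConfig()
        iv = GenomicInterval("2", 2_990_000, 3_062_000)
        calls = generate_algorithm_calls([("S1", iv, "deletion")], cfg, seed=3)
        flat = [c for cl in calls.values() for c in cl]
        assert len(flat) >= 2
        for a in flat:
            for b in flat:
                assert reciprocal_overlap(a.interval, b.interval) > 0.9
        assert {c.algorithm for c in flat} & {"ChAS", "iPattern"}

    def test_probe_counts_track_length(self):
        cfg = CohortConfig()
        iv = GenomicInterval("2", 0, 72_000)
        calls = generate_algorithm_calls([("S1", iv, "deletion")], cfg, seed=3)
        for c in (c for cl in calls.values() for c in cl):
            assert c.n_probes == -(-c.interval.length // cfg.probe_spacing_bp)


class TestControls:
    def test_cohort_size_and_common_loci(self):
        cfg = CohortConfig()
        calls, n = generate_control_cohort(cfg, seed=5)
        assert n == 873
        # 5% locus: carrier count near binomial expectation
        locus = cfg.common_loci[0]
        carriers = {
            c.sample_id for c in calls
            if reciprocal_overlap(c.interval, locus.interval) >= 0.5
            and c.copy_state == locus.copy_state
        }
        expect = 873 * locus.frequency
        sd = np.sqrt(873 * locus.frequency * (1 - locus.frequency))
        assert abs(len(carriers) - expect) < 4 * sd

    def test_planted_rare_loci_absent_from_controls(self, bundle):
        control_calls = read_cnv_calls(bundle.controls)
        for entry in bundle.ground_truth_entries:
            if entry.category != "relevant":
                continue
            for c in control_calls:
                assert reciprocal_overlap(c.interval, entry.interval) < 0.5


class TestGroundTruthRecovery:
    def test_planted_carriers_recovered_exactly(self, bundle, pipeline_result):
        """Classified sibling/proband carriers equal the ledger's intent:
        every planted relevant CNV gets its intended tier, and nothing else
        is classified above not_relevant."""
        expected = {
            (e.sample_id, e.interval.chrom, e.copy_state): e.expected_tier
            for e in bundle.ground_truth_entries
            if e.category == "relevant"
        }
        got = {}
        for idx, cls in pipeline_result.classifications.items():
            cnv = pipeline_result.consensus[idx]
            if cls.tier == "not_relevant":
                continue
            if cnv.sample_id.endswith(("mother", "father")):
                continue  # transmitting parents legitimately carry the CNV too
            got[(cnv.sample_id, cnv.interval.chrom, cnv.copy_state)] = cls.tier
        assert got == expected

    def test_artifacts_never_reach_consensus(self, bundle, pipeline_result):
        artifact_keys = {
            (e.sample_id, e.interval.chrom)
            for e in bundle.ground_truth_entries
            if e.category == "artifact"
        }
        consensus_keys = {
            (c.sample_id, c.interval.chrom) for c in pipeline_result.consensus
        }
        assert artifact_keys.isdisjoint(consensus_keys)

    def test_common_variants_marked_common(self, bundle, pipeline_result):
        common_samples = {
            e.sample_id for e in bundle.ground_truth_entries if e.category == "common"
        }
        seen = 0
        for c in pipeline_result.consensus:
            if c.sample_id in common_samples and c.rarity == "common":
                seen += 1
        assert seen == len(common_samples)

    def test_inheritance_annotations_match_plan(self, bundle, pipeline_result):
        planned = {
            (e.sample_id, e.interval.chrom): e.inheritance
            for e in bundle.ground_truth_entries
            if e.category == "relevant"
        }
        for idx, cls in pipeline_result.classifications.items():
            cnv = pipeline_result.consensus[idx]
            key = (cnv.sample_id, cnv.interval.chrom)
            if key in planned and cls.tier != "not_relevant":
                assert cnv.inheritance == planned[key]
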