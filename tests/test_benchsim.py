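"""Synthetic proteome generation, dataset simulation and SN/FPX metrics."""

import numpy as np
import pandas as pd
import pytest

from slimq.benchsim import (
    BenchError,
    ProteomeParams,
    SimDatasetSpec,
    build_elmbench,
    build_simbench,
    compute_metrics,
    generate_proteome,
    implant_instance,
    verify_signal_unrelated,
)
from slimq.seqdata import ProteinRecord, disorder_mask
from slimq.slimbuild import find_occurrences, parse_pattern
from slimq.seqdata import no_mask
from slimq.upc import partition_dataset


class TestGenerateProteome:
    def test_deterministic(self):
        params = ProteomeParams(n_proteins=5, seed=99)
        a = generate_proteome(params)
        b = generate_proteome(params)
        assert [(r.id, r.sequence, r.disorder) for r in a] == [
            (r.id, r.sequence, r.disorder) for r in b
        ]

    def test_singletons_unrelated(self):
        proteome = generate_proteome(ProteomeParams(n_proteins=10, seed=3))
        assert partition_dataset(proteome).n == 10

    def test_family_forms_one_cluster(self):
        proteome = generate_proteome(
            ProteomeParams(n_proteins=0, n_families=1, family_size=3,
                           family_mutation_rate=0.05, seed=3)
        )
        assert len(proteome) == 3
        assert partition_dataset(proteome).n == 1

    def test_disorder_block_structure(self):
        proteome = generate_proteome(ProteomeParams(n_proteins=3, seed=1))
        for record in proteome:
            assert len(record.disorder) == len(record)
            assert all(0.0 <= s <= 1.0 for s in record.disorder)
            # blocks are >= 5 residues, so smoothing never alters the mask
            masked = disorder_mask(record)
            raw = tuple(s < 0.2 for s in record.disorder)
            assert masked.mask == raw


class TestImplantInstance:
    def test_fixed_pattern_exact(self, rng):
        record = generate_proteome(ProteomeParams(n_proteins=1, seed=7))[0]
        implanted = implant_instance(record, "DWFCT", rng)
        start, end = implanted.annotations["instance"]
        assert implanted.sequence[start - 1 : end] == "DWFCT"

    def test_degenerate_pattern_matches_itself(self, rng):
        motif = parse_pattern("Q.[IL].FF")
        record = generate_proteome(ProteomeParams(n_proteins=1, seed=8))[0]
        implanted = implant_instance(record, motif, rng)
        start, end = implanted.annotations["instance"]
        occs = find_occurrences(motif, no_mask(implanted))
        assert any(o.start == start for o in occs)

    def test_span_fully_disordered(self, rng):
        record = generate_proteome(ProteomeParams(n_proteins=1, seed=9))[0]
        implanted = implant_instance(record, "DWFCT", rng)
        start, end = implanted.annotations["instance"]
        assert all(s >= 0.2 for s in implanted.disorder[start - 1 : end])

    def test_no_eligible_block_error(self, rng):
        record = ProteinRecord("P1", "A" * 50, (0.0,) * 50)
        with pytest.raises(BenchError):
            implant_instance(record, "DWFCT", rng)


@pytest.fixture(scope="module")
def proteome():
    return generate_proteome(ProteomeParams(n_proteins=120, seed=2026))


class TestBuildSimbench:
    def test_signal_only_dataset(self, proteome):
        spec = SimDatasetSpec(motif="DWFCT", signal=5, ratio="1:0", seed=1)
        positive, negative = build_simbench(proteome, spec)
        assert len(positive.records) == 5
        assert all(v == "signal" for v in positive.labels.values())
        assert verify_signal_unrelated(positive)

    def test_one_to_nine_total(self, proteome):
        spec = SimDatasetSpec(motif="DWFCT", signal=10, ratio="1:9", seed=2)
        positive, _ = build_simbench(proteome, spec)
        assert len(positive.records) == 100
        assert sum(v == "signal" for v in positive.labels.values()) == 10

    def test_paired_negative_contract(self, proteome):
        spec = SimDatasetSpec(motif="DWFCT", signal=5, ratio="1:1", seed=3)
        positive, negative = build_simbench(proteome, spec)
        assert negative.query_id == positive.query_id
        assert len(negative.records) == len(positive.records)
        # only the shared query carries an implant in the negative twin
        implanted = [r for r in negative.records if "instance" in r.annotations]
        assert [r.id for r in implanted] == [negative.query_id]

    def test_all_signal_proteins_implanted(self, proteome):
        spec = SimDatasetSpec(motif="DWFCT", signal=5, ratio="1:0", seed=4)
        positive, _ = build_simbench(proteome, spec)
        for record in positive.records:
            start, end = record.annotations["instance"]
            assert record.sequence[start - 1 : end] == "DWFCT"

    def test_insufficient_proteome_error(self):
        tiny = generate_proteome(ProteomeParams(n_proteins=4, seed=5))
        spec = SimDatasetSpec(motif="DWFCT", signal=5, ratio="1:0", seed=5)
        with pytest.raises(BenchError):
            build_simbench(tiny, spec)

    def test_reproducible_from_seed(self, proteome):
        spec = SimDatasetSpec(motif="DWFCT", signal=5, ratio="1:1", seed=6)
        a_pos, a_neg = build_simbench(proteome, spec)
        b_pos, b_neg = build_simbench(proteome, spec)
        assert [r.sequence for r in a_pos.records] == [
            r.sequence for r in b_pos.records
        ]
        assert [r.id for r in a_neg.records] == [r.id for r in b_neg.records]


class TestBuildElmbench:
    def make_records(self, n):
        rng = np.random.default_rng(0)
        proteome = generate_proteome(ProteomeParams(n_proteins=n, seed=17))
        return [implant_instance(r, "DWFCT", rng) for r in proteome]

    def test_seven_records_six_strategies(self):
        jobs = build_elmbench(self.make_records(7))
        assert len(jobs) == 42
        assert len({(j.query_id, j.strategy) for j in jobs}) == 42

    def test_site_region_equals_instance(self):
        records = self.make_records(2)
        jobs = [j for j in build_elmbench(records) if j.strategy == "site"]
        for job, record in zip(jobs, records):
            assert (job.region.start, job.region.end) == record.annotations[
                "instance"
            ]

    def test_none_region_full_protein(self):
        records = self.make_records(1)
        job = next(j for j in build_elmbench(records) if j.strategy == "none")
        assert (job.region.start, job.region.end) == (1, len(records[0]))

    def test_missing_annotation_error(self):
        record = generate_proteome(ProteomeParams(n_proteins=1, seed=1))[0]
        with pytest.raises(BenchError, match="instance"):
            build_elmbench([record])


class TestComputeMetrics:
    def test_simple_proportions(self):
        ratings = pd.DataFrame(
            {
                "motif": ["M1"] * 20,
                "kind": ["positive"] * 10 + ["negative"] * 10,
                "rating": ["TP"] * 7 + [None] * 3 + [None] * 10,
            }
        )
        row = compute_metrics(ratings).iloc[0]
        assert row["SN"] == pytest.approx(0.7)
        assert row["FPX"] == pytest.approx(0.0)

    def test_ot_counts_in_neither_numerator(self):
        ratings = pd.DataFrame(
            {
                "motif": ["M1"] * 4,
                "kind": ["positive", "positive", "negative", "negative"],
                "rating": ["OT", "TP", "OT", "FP"],
            }
        )
        row = compute_metrics(ratings).iloc[0]
        assert row["SN"] == pytest.approx(0.5)
        assert row["FPX"] == pytest.approx(0.5)

    def test_mean_of_means_normalisation(self):
        # M1: 2/2 TP; M2: 3/6 TP -> plain SN 5/8, normalised (1.0+0.5)/2
        ratings = pd.DataFrame(
            {
                "motif": ["M1"] * 2 + ["M2"] * 6,
                "kind": ["positive"] * 8,
                "rating": ["TP", "TP", "TP", "TP", "TP", None, None, None],
            }
        )
        plain = compute_metrics(ratings).iloc[0]
        norm = compute_metrics(ratings, normalise_by_motif=True).iloc[0]
        assert plain["SN"] == pytest.approx(5 / 8)
        assert norm["SN"] == pytest.approx(0.75)

    def test_empty_group_flagged_nan(self):
        ratings = pd.DataFrame(
            {"motif": ["M1"], "kind": ["positive"], "rating": ["TP"]}
        )
        row = compute_metrics(ratings).iloc[0]
        assert np.isnan(row["FPX"])

    def test_missing_columns_error(self):
        with pytest.raises(BenchError):
            compute_metrics(pd.DataFrame({"motif": []}))
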