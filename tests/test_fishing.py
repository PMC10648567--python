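"""Tests for stage 1: similarity gate, affinity filter, disease join."""

import pytest

from scaforge import chem, datagen, fishing, oracles


@pytest.fixture(scope="module")
def loaded(bundle_dir):
    ds = fishing.load_dataset(bundle_dir)
    dt = fishing.load_disease_table(bundle_dir)
    spec = oracles.SurrogateSpec.from_yaml((bundle_dir / "oracle_spec.yaml").read_text())
    return ds, dt, oracles.surrogate_affinity(spec)


class _ConstOracle:
    """Stub oracle with a fixed score per (drug, sequence) pair."""

    def __init__(self, table, default=0.0):
        self.table = table
        self.default = default

    def score(self, drug_smiles, target_sequence):
        return self.table.get((drug_smiles, target_sequence), self.default)


def _tiny_dataset():
    drugs = [
        ("D1", chem.canonicalize("CCO")),
        ("D2", chem.canonicalize("CCN")),
    ]
    targets = [("T1", "MKTA"), ("T2", "ACDE")]
    edges = {("D1", "T1"), ("D2", "T1")}
    return fishing.InteractionDataset(drugs=drugs, targets=targets, edges=edges)


class TestFindSimilarDrugs:
    def test_recovers_exactly_planted_neighbors(self, scenario, loaded, cbd):
        _, _, truth = scenario
        ds, _, _ = loaded
        hits = fishing.find_similar_drugs(cbd, ds, 0.4)
        assert sorted(d for d, _ in hits) == sorted(truth.planted_similar_ids)

    def test_matches_brute_force_similarity_scan(self, loaded, cbd):
        ds, _, _ = loaded
        hits = dict(fishing.find_similar_drugs(cbd, ds, 0.4))
        for drug_id, mol in ds.drugs:
            sim = chem.avg_tanimoto(cbd, mol)
            if mol == cbd:
                assert drug_id not in hits
            elif sim > 0.4:
                assert hits[drug_id] == pytest.approx(sim)
            else:
                assert drug_id not in hits

    def test_threshold_one_yields_nothing(self, loaded, cbd):
        ds, _, _ = loaded
        assert fishing.find_similar_drugs(cbd, ds, 1.0) == []

    def test_query_structure_self_excluded(self, cbd):
        ds = fishing.InteractionDataset(
            drugs=[("ME", cbd)], targets=[("T1", "MKTA")], edges=set()
        )
        assert fishing.find_similar_drugs(cbd, ds, 0.0) == []

    def test_sorted_by_descending_similarity(self, loaded, cbd):
        ds, _, _ = loaded
        sims = [s for _, s in fishing.find_similar_drugs(cbd, ds, 0.4)]
        assert sims == sorted(sims, reverse=True)


class TestCollectCandidateTargets:
    def test_shared_target_collapses_to_singleton(self):
        ds = _tiny_dataset()
        assert fishing.collect_candidate_targets([("D1", 0.9), ("D2", 0.8)], ds) == {"T1"}

    def test_drug_without_edges_contributes_nothing(self):
        ds = _tiny_dataset()
        ds.edges.discard(("D2", "T1"))
        assert fishing.collect_candidate_targets([("D2", 0.8)], ds) == set()

    def test_scenario_candidates_match_edge_table(self, scenario, loaded):
        _, _, truth = scenario
        ds, _, _ = loaded
        similar = [(d, 1.0) for d in truth.planted_similar_ids]
        assert fishing.collect_candidate_targets(similar, ds) == set(
            truth.expected_candidate_targets
        )


class TestFilterByAffinity:
    def _run(self, q_score, s_score, cutoff=4.0, **kwargs):
        ds = _tiny_dataset()
        query = chem.canonicalize("c1ccccc1O")
        oracle = _ConstOracle(
            {
                (query.smiles_canonical, "MKTA"): q_score,
                (ds.drug_by_id["D1"].smiles_canonical, "MKTA"): s_score,
            }
        )
        return fishing.filter_by_affinity(
            query, {"T1"}, [("D1", 0.8)], ds, oracle, cutoff=cutoff, **kwargs
        )

    def test_both_above_cutoff_retained(self):
        kept = self._run(5.0, 4.5)
        assert [c.accession for c in kept] == ["T1"]
        assert kept[0].pic50_query == 5.0
        assert kept[0].supporting == [("D1", 0.8, 4.5)]

    def test_query_below_cutoff_excluded(self):
        assert self._run(3.9, 6.0) == []

    def test_exactly_at_cutoff_excluded(self):
        assert self._run(4.0, 6.0) == []
        assert self._run(6.0, 4.0) == []

    def test_all_supporters_variant_is_stricter(self):
        ds = _tiny_dataset()
        query = chem.canonicalize("c1ccccc1O")
        oracle = _ConstOracle(
            {
                (query.smiles_canonical, "MKTA"): 6.0,
                (ds.drug_by_id["D1"].smiles_canonical, "MKTA"): 6.0,
                (ds.drug_by_id["D2"].smiles_canonical, "MKTA"): 3.0,
            }
        )
        similar = [("D1", 0.8), ("D2", 0.7)]
        permissive = fishing.filter_by_affinity(query, {"T1"}, similar, ds, oracle)
        strict = fishing.filter_by_affinity(
            query, {"T1"}, similar, ds, oracle, require_all_supporters=True
        )
        assert [c.accession for c in permissive] == ["T1"]
        assert strict == []


class TestMapToDisease:
    def _table(self):
        return fishing.DiseaseTable(
            associations=[
                ("GENE1", "Alzheimer disease 2"),
                ("GENE2", "Hypertension"),
            ],
            xref={"T1": "GENE1", "T2": "GENE2"},
        )

    def test_substring_match_case_insensitive(self):
        cands = [fishing.CandidateTarget("T1", 5.0)]
        out = fishing.map_to_disease(cands, self._table(), "alzheimer")
        assert len(out) == 1 and out[0].disease_matched
        assert out[0].gene_symbol == "GENE1"

    def test_unrelated_phenotype_excluded(self):
        cands = [fishing.CandidateTarget("T2", 5.0)]
        assert fishing.map_to_disease(cands, self._table(), "Alzheimer") == []

    def test_missing_xref_excluded(self):
        cands = [fishing.CandidateTarget("T9", 5.0)]
        assert fishing.map_to_disease(cands, self._table(), "Alzheimer") == []


class TestRunTargetIdentification:
    def test_recovers_planted_disease_targets(self, scenario, loaded, cbd):
        _, _, truth = scenario
        ds, dt, oracle = loaded
        report = fishing.run_target_identification(cbd, ds, dt, oracle)
        assert sorted(report["accession"]) == sorted(truth.expected_final_targets)

    def test_reported_evidence_satisfies_filters(self, loaded, cbd):
        ds, dt, oracle = loaded
        report = fishing.run_target_identification(cbd, ds, dt, oracle)
        for _, row in report.iterrows():
            assert row["pic50_query"] > 4.0
            assert row["pic50_support"] > 4.0
            assert row["similarity"] > 0.4
            assert "alzheimer" in row["phenotype"].lower()

    def test_deterministic_report(self, loaded, cbd, tmp_path):
        ds, dt, oracle = loaded
        paths = []
        for i in (1, 2):
            df = fishing.run_target_identification(cbd, ds, dt, oracle)
            p = tmp_path / f"report{i}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_unmatched_phenotype_gives_empty_table(self, loaded, cbd):
        ds, dt, oracle = loaded
        cfg = fishing.PipelineConfig(phenotype_query="no-such-disease")
        report = fishing.run_target_identification(cbd, ds, dt, oracle, cfg)
        assert len(report) == 0
        assert list(report.columns) == fishing.REPORT_COLUMNS

    @pytest.mark.parametrize("sim_thr, aff_cut", [(0.45, 4.0), (0.4, 4.5), (0.6, 5.5)])
    def test_monotone_in_thresholds(self, loaded, cbd, sim_thr, aff_cut):
        """Raising either threshold never enlarges the output set."""
        ds, dt, oracle = loaded
        base = set(
            fishing.run_target_identification(cbd, ds, dt, oracle)["accession"]
        )
        tighter = set(
            fishing.run_target_identification(
                cbd, ds, dt, oracle,
                fishing.PipelineConfig(similarity_threshold=sim_thr, affinity_cutoff=aff_cut),
            )["accession"]
        )
        assert tighter <= base


class TestLoaders:
    def test_malformed_smi_names_file_and_line(self, tmp_path):
        p = tmp_path / "drugs.smi"
        p.write_text("CCO D1\nnot-a-smiles( D2\n")
        with pytest.raises(fishing.DataFormatError, match=r"drugs\.smi:2"):
            fishing.read_smi(p)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "interactions.tsv"
        p.write_text("D1\tT1\n")
        with pytest.raises(fishing.DataFormatError, match="header"):
            fishing._read_two_column_tsv(p, ("drug_id", "accession"))

    def test_edge_to_unknown_target_rejected(self):
        with pytest.raises(fishing.DataFormatError, match="unknown"):
            fishing.InteractionDataset(
                drugs=[("D1", chem.canonicalize("CCO"))],
                targets=[("T1", "MKTA")],
                edges={("D1", "T9")},
            )
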