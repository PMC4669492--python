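"""Genotyping path: dedup, pileup, calling thresholds, SNP filters, VCF."""

import numpy as np
import pandas as pd
import pytest

from spinachseq import genotyping as gt
from spinachseq import synthetic_data as sd


def _rec(contig, start, seq, acc="acc1", strand="+"):
    return gt.AlignmentRecord(contig, start, strand, seq, acc)


class TestDeduplicate:
    def test_identical_records_collapse_to_one(self):
        records = [_rec("c1", 5, "ACGT")] * 5
        assert len(gt.deduplicate_reads(records)) == 1

    def test_same_start_different_sequence_kept(self):
        records = [_rec("c1", 5, "ACGT"), _rec("c1", 5, "ACGA")]
        assert len(gt.deduplicate_reads(records)) == 2

    def test_mixed_duplicate_groups(self):
        # hand count: duplicate groups of sizes 3 and 2 plus 5 singletons
        # -> 2 + 5 = 7 distinct (accession, contig, start, strand, sequence) tuples
        records = (
            [_rec("c1", 1, "AAAA")] * 3
            + [_rec("c1", 2, "CCCC")] * 2
            + [_rec("c1", 3, "GGGG")]
            + [_rec("c2", i, "TTTT") for i in range(1, 5)]
        )
        assert len(records) == 10
        assert len(gt.deduplicate_reads(records)) == 7

    def test_idempotent(self):
        records = [_rec("c1", 1, "AAAA")] * 3 + [_rec("c1", 2, "ACGT")]
        once = gt.deduplicate_reads(records)
        twice = gt.deduplicate_reads(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_per_accession_keys(self):
        records = [_rec("c1", 1, "ACGT", acc="a"), _rec("c1", 1, "ACGT", acc="b")]
        assert len(gt.deduplicate_reads(records)) == 2


class TestPileup:
    def test_single_read_three_observations(self):
        obs = gt.pileup([_rec("c1", 1, "ACG")])
        assert len(obs) == 3
        assert obs["pos"].tolist() == [1, 2, 3]
        assert obs[["count_A", "count_C", "count_G"]].to_numpy().diagonal().tolist() == [1, 1, 1]
        assert (obs[gt.COUNT_COLUMNS].sum(axis=1) == 1).all()

    def test_overlapping_reads_mixed_bases(self):
        obs = gt.pileup([_rec("c1", 1, "A"), _rec("c1", 1, "C")])
        row = obs.iloc[0]
        assert (row["count_A"], row["count_C"], row["count_G"], row["count_T"]) == (1, 1, 0, 0)

    def test_non_acgt_bases_ignored(self):
        obs = gt.pileup([_rec("c1", 1, "ANG")])
        assert obs["pos"].tolist() == [1, 3]

    def test_read_past_contig_end_rejected(self):
        with pytest.raises(ValueError, match="beyond contig"):
            gt.pileup([_rec("c1", 8, "ACGT")], contig_lengths={"c1": 10})

    def test_error_free_simulation_matches_planted_counts(self, scenario):
        cfg = sd.SimulationConfig(
            n_unigenes=60, n_snp_sites=50, base_error_rate=0.0, min_depth=3, seed=8
        )
        truth = sd.plant_genotypes(sd.generate_unigenes(cfg), scenario, cfg)
        records, obs = sd.simulate_pileups(truth, cfg)
        recomputed = gt.pileup(gt.deduplicate_reads(records))
        pd.testing.assert_frame_equal(obs, recomputed)
        geno = truth.planted_site_genotypes
        indexed = recomputed.set_index(["contig", "pos", "accession"])
        for contig, pos in truth.planted_sites:
            for acc in geno.index:
                row = indexed.loc[(contig, pos, acc)]
                majority = "ACGT"[int(np.argmax([row[c] for c in gt.COUNT_COLUMNS]))]
                assert majority == geno.loc[acc, (contig, pos)]
                assert sum(row[c] > 0 for c in gt.COUNT_COLUMNS) == 1


class TestCallGenotype:
    def _obs(self, **counts):
        return gt.SiteObservation("c1", 10, "acc1", counts)

    def test_clear_majority_called(self):
        call = gt.call_genotype(self._obs(A=5, C=1))
        assert call.state == "called" and call.allele == "A"
        assert call.supporting_reads == 5
        assert call.allele_frequency == pytest.approx(5 / 6)

    def test_exact_threshold_is_ambiguous(self):
        # frequency must exceed 0.75 strictly: 3/4 fails
        call = gt.call_genotype(self._obs(A=3, G=1))
        assert call.state == "ambiguous"

    def test_shallow_site_missing(self):
        assert gt.call_genotype(self._obs(T=2)).state == "missing"

    def test_min_reads_applies_to_majority_allele(self):
        # depth 4 but majority only 2 reads -> ambiguous, not called
        assert gt.call_genotype(self._obs(A=2, C=1, G=1)).state == "ambiguous"

    def test_threshold_perturbation_flips_only_exact_boundary(self):
        frame = pd.DataFrame(
            {
                "contig": ["c"] * 3,
                "pos": [1, 2, 3],
                "accession": ["a"] * 3,
                "count_A": [3, 4, 9],
                "count_C": [1, 1, 1],
                "count_G": [0, 0, 0],
                "count_T": [0, 0, 0],
            }
        )
        strict = gt.call_genotypes(frame, min_freq=0.75)
        relaxed = gt.call_genotypes(frame, min_freq=0.7499)
        changed = strict["state"] != relaxed["state"]
        ratio = frame["count_A"] / frame[gt.COUNT_COLUMNS].sum(axis=1)
        assert (changed == (ratio == 0.75)).all()

    def test_invalid_min_freq_rejected(self):
        with pytest.raises(ValueError, match="min_freq"):
            gt.call_genotype(self._obs(A=5), min_freq=1.0)


class TestSnpSites:
    def _calls(self, alleles_by_acc, pos=1):
        rows = []
        for acc, allele in alleles_by_acc.items():
            counts = {c: 0 for c in gt.COUNT_COLUMNS}
            if allele is not None:
                counts[f"count_{allele}"] = 10
            rows.append({"contig": "c1", "pos": pos, "accession": acc, **counts})
        return gt.call_genotypes(pd.DataFrame(rows))

    def test_two_alleles_is_snp(self):
        table = gt.identify_snp_sites(self._calls({"a": "A", "b": "A", "c": "G"}))
        assert len(table) == 1
        assert set(table.iloc[0]) == {"A", "G"}

    def test_missing_does_not_create_snp(self):
        table = gt.identify_snp_sites(self._calls({"a": "A", "b": "A", "c": None}))
        assert table.empty

    def test_error_free_recovery_equals_planted_sites(self, scenario):
        cfg = sd.SimulationConfig(
            n_unigenes=80, n_snp_sites=60, base_error_rate=0.0, min_depth=3, seed=23
        )
        truth = sd.plant_genotypes(sd.generate_unigenes(cfg), scenario, cfg)
        _, obs = sd.simulate_pileups(truth, cfg)
        table = gt.identify_snp_sites(gt.call_genotypes(obs))
        assert set(table.index) == set(truth.planted_sites)
        geno = truth.planted_site_genotypes
        for acc in geno.index:
            recovered = table[acc].sort_index()
            expected = geno.loc[acc]
            expected.index = pd.MultiIndex.from_tuples(
                geno.columns, names=["contig", "pos"]
            )
            pd.testing.assert_series_equal(
                recovered, expected.sort_index(), check_names=False
            )


class TestFilters:
    def _random_table(self, seed, n_acc=9, n_sites=200, missing=0.15):
        rng = np.random.default_rng(seed)
        alleles = rng.choice(list("ACGT"), size=2)
        data = rng.choice(alleles, size=(n_sites, n_acc)).astype(object)
        mask = rng.random((n_sites, n_acc)) < missing
        data[mask] = np.nan
        idx = pd.MultiIndex.from_tuples(
            [("c1", i + 1) for i in range(n_sites)], names=["contig", "pos"]
        )
        return pd.DataFrame(data, index=idx, columns=[f"a{i}" for i in range(n_acc)])

    def test_filter_complete_matches_brute_force(self):
        table = self._random_table(31)
        accs = list(table.columns)
        result = gt.filter_complete(table, accs)
        expected = [
            site for site, row in table.iterrows() if row.notna().all()
        ]
        assert list(result.index) == expected
        assert not result.isna().any().any()

    def test_incomplete_site_excluded(self):
        table = self._random_table(5, n_sites=10, missing=0.5)
        result = gt.filter_complete(table, list(table.columns))
        assert all(table.loc[s].notna().all() for s in result.index)

    def test_empty_accession_list_rejected(self):
        with pytest.raises(ValueError):
            gt.filter_complete(self._random_table(1), [])

    def test_single_site_group_counts(self):
        idx = pd.MultiIndex.from_tuples([("c1", 1)], names=["contig", "pos"])
        table = pd.DataFrame([["A", "A", "G"]], index=idx, columns=["a1", "a2", "a3"])
        counts = gt.count_group_snps(
            table, {"trio": ["a1", "a2", "a3"], "pair": ["a1", "a2"]}
        )
        assert counts["trio"] == 1 and counts["pair"] == 0

    def test_group_counts_match_brute_force_and_monotone(self):
        rng = np.random.default_rng(42)
        table = self._random_table(42, n_acc=8, n_sites=200, missing=0.0)
        groups = {"g1": ["a0", "a1", "a2"], "g2": ["a3", "a4", "a5"], "g3": ["a6", "a7"]}
        unions = {"g1+g2": ("g1", "g2"), "all": ("g1", "g2", "g3")}
        counts = gt.count_group_snps(table, groups, unions)
        # independent double loop
        for name, accs in {**groups,
                           "g1+g2": groups["g1"] + groups["g2"],
                           "all": sum(groups.values(), [])}.items():
            brute = 0
            for _, row in table.iterrows():
                seen = {row[a] for a in accs if pd.notna(row[a])}
                brute += len(seen) >= 2
            assert counts[name] == brute
        assert counts["g1"] <= counts["g1+g2"] <= counts["all"]
        assert counts["g2"] <= counts["g1+g2"]

    def test_unknown_accession_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            gt.count_group_snps(self._random_table(1), {"g": ["nope"]})


class TestVcf:
    def _table(self, rows, accs):
        idx = pd.MultiIndex.from_tuples(
            [("c1", i + 1) for i in range(len(rows))], names=["contig", "pos"]
        )
        return pd.DataFrame(rows, index=idx, columns=accs)

    def test_ref_alt_and_genotypes(self, tmp_path):
        table = self._table([["A", "A", "G"]], ["x", "y", "z"])
        path = tmp_path / "out.vcf"
        gt.write_vcf(table, path)
        data_line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        fields = data_line.split("\t")
        assert fields[3] == "A" and fields[4] == "G"
        assert fields[9:] == ["0/0", "0/0", "1/1"]

    def test_ref_tie_broken_alphabetically(self, tmp_path):
        table = self._table([["G", "A", "G", "A"]], list("wxyz"))
        path = tmp_path / "tie.vcf"
        gt.write_vcf(table, path)
        data_line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert data_line.split("\t")[3] == "A"

    def test_round_trip_through_pysam(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        rng = np.random.default_rng(7)
        accs = [f"s{i}" for i in range(5)]
        rows = []
        for _ in range(40):
            pair = rng.choice(list("ACGT"), size=2, replace=False)
            row = rng.choice(pair, size=5).astype(object)
            if rng.random() < 0.3:
                row[rng.integers(5)] = np.nan
            if len(set(row[pd.notna(row)])) < 2:
                row[0], row[1] = pair[0], pair[1]
            rows.append(row)
        table = self._table(rows, accs)
        path = tmp_path / "round.vcf"
        gt.write_vcf(table, path)
        back = {}
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                alleles = [rec.ref] + list(rec.alts or [])
                for s in samples:
                    idx = rec.samples[s]["GT"][0]
                    back[(rec.chrom, rec.pos, s)] = (
                        None if idx is None else alleles[idx]
                    )
        for (contig, pos), row in table.iterrows():
            for acc in accs:
                expected = None if pd.isna(row[acc]) else row[acc]
                assert back[(contig, pos, acc)] == expected


def test_pileup_tsv_round_trip(tmp_path):
    obs = gt.pileup([_rec("c1", 1, "ACG"), _rec("c1", 2, "CGT", acc="acc2")])
    path = tmp_path / "pileup.tsv"
    gt.write_pileup_tsv(obs, path)
    header = path.read_text().splitlines()[0].split("\t")
    assert header == gt.PILEUP_COLUMNS
    back = gt.read_pileup_tsv(path)
    pd.testing.assert_frame_equal(obs, back)
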