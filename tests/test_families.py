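import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from evomine import families as fm
from evomine.families import CopyTable
from evomine.fixtures import mutate
from evomine.records import Genome, ProteinRecord
from evomine.search import Thresholds

from .conftest import random_protein
from .oracles import expansion_stats_oracle


def _table(counts_by_family, genomes):
    df = pd.DataFrame.from_dict(counts_by_family, orient="index",
                                columns=genomes)
    return CopyTable(df)


class TestExpansionStats:
    def test_worked_example_mean_plus_two_sd(self):
        genomes = [f"g{i}" for i in range(6)]
        table = _table({"fam": [1, 1, 1, 1, 1, 8]}, genomes)
        (st,) = fm.expansion_stats(table)
        assert st.mean_all == pytest.approx(13 / 6)
        assert st.sd_all == pytest.approx(2.6087, abs=1e-3)
        # threshold mean + 2 SD ~ 7.384: only the 8-copy genome is beyond it
        assert st.significant_genomes == {"g5"}

    def test_extra_copies_beyond_mode(self):
        genomes = [f"g{i}" for i in range(7)]
        table = _table({"fam": [1, 1, 2, 2, 2, 3, 5]}, genomes)
        (st,) = fm.expansion_stats(table)
        assert st.mode == 2
        assert st.extra_copy_genomes == {"g5", "g6"}

    @pytest.mark.parametrize(
        "counts,klass",
        [([1] * 6 + [0] * 4, "shell"), ([1] * 10, "core"),
         ([1] * 5 + [0] * 5, "cloud"), ([2] * 3 + [0] * 7, "cloud")],
    )
    def test_core_shell_cloud(self, counts, klass):
        genomes = [f"g{i}" for i in range(10)]
        (st,) = fm.expansion_stats(_table({"f": counts}, genomes))
        assert st.conservation_class == klass

    def test_single_genome_disables_significance(self, caplog):
        (st,) = fm.expansion_stats(_table({"f": [4]}, ["g0"]))
        assert st.sd_all == 0.0
        assert st.significant_genomes == set()
        assert not st.significance_enabled

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(6, 60))
            counts = rng.integers(0, 16, size=n).tolist()
            genomes = [f"g{i}" for i in range(n)]
            (st,) = fm.expansion_stats(_table({"f": counts}, genomes))
            exp = expansion_stats_oracle(counts, genomes)
            assert st.mean_all == pytest.approx(exp["mean_all"])
            assert st.sd_all == pytest.approx(exp["sd_all"])
            assert st.mode == exp["mode"]
            assert st.significant_genomes == exp["significant"]
            assert st.extra_copy_genomes == exp["extra"]
            assert st.conservation_class == exp["class"]

    def test_class_partition_is_total_and_exclusive(self, bundle, expanded):
        table = fm.copy_table(list(expanded.values()), bundle.genomes)
        stats = fm.expansion_stats(table)
        for st in stats:
            assert st.conservation_class in {"core", "shell", "cloud"}


class TestCopyTable:
    def test_row_and_column_sums(self, bundle, expanded):
        fams = list(expanded.values())
        table = fm.copy_table(fams, bundle.genomes)
        for fam in fams:
            assert table.df.loc[fam.family_id].sum() == len(fam.members)
        for g in bundle.genomes:
            total = sum(
                1 for fam in fams for m in fam.members
                if m.genome_id == g.genome_id
            )
            assert table.df[g.genome_id].sum() == total

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CopyTable(pd.DataFrame({"g0": [-1]}, index=["f"]))


class TestExpandFamily:
    def test_fixture_counts_match_plan(self, bundle, expanded):
        table = fm.copy_table(list(expanded.values()), bundle.genomes)
        # fam-a: one conserved copy everywhere plus 5 extras in g00
        assert table.df.loc["fam-a", "g00"] == 6
        assert all(table.df.loc["fam-a"].drop("g00") == 1)
        # fam-b: shell pattern with recruited copies in g01/g02
        assert table.df.loc["fam-b", "g07":].sum() == 0
        assert table.df.loc["fam-b", "g01"] == 2

    def test_membership_equals_brute_force(self, bundle, expanded):
        from .oracles import sw_score

        fam = bundle.enzyme_db[1]  # fam-b, single seed
        seed = fam.seeds[0].sequence
        all_proteins = [p for g in bundle.genomes for p in g.proteins]
        n_db = sum(len(p.sequence) for p in all_proteins)
        lam, K = 0.267, 0.041
        expected = set()
        for p in all_proteins:
            bits = (lam * sw_score(seed, p.sequence) - np.log(K)) / np.log(2)
            if bits >= 100 and len(seed) * n_db * 2.0 ** (-bits) <= 0.001:
                expected.add(p.protein_id)
        got = {m.protein_id for m in expanded["fam-b"].members}
        assert got == expected

    def test_monotone_in_thresholds(self, bundle, expanded):
        fam = bundle.enzyme_db[0]
        strict = {m.protein_id for m in expanded["fam-a"].members}
        relaxed = fm.expand_family(
            fam, bundle.genomes, Thresholds(max_evalue=0.01, min_bitscore=50)
        )
        assert strict <= {m.protein_id for m in relaxed.members}

    def test_members_deduplicated_with_two_seeds(self, bundle):
        fam = bundle.enzyme_db[0]
        doubled = fm.EnzymeFamily(
            family_id=fam.family_id, seeds=[
                fam.seeds[0],
                ProteinRecord(
                    protein_id="seed2", genome_id="seedref", contig_id="s",
                    start=1, end=3 * len(fam.seeds[0].sequence), strand="+",
                    sequence=fam.seeds[0].sequence,
                ),
            ],
        )
        expanded_two = fm.expand_family(doubled, bundle.genomes)
        ids = [m.protein_id for m in expanded_two.members]
        assert len(ids) == len(set(ids))


class TestBuildEnzymeDb:
    def test_shared_families_retained(self):
        rng = np.random.default_rng(21)
        refs = []
        seed_seqs = {}
        for i in range(5):
            seq = random_protein(rng, 250)
            seed_seqs[f"fam{i}"] = seq
            refs.append(fm.EnzymeFamily(
                family_id=f"fam{i}",
                seeds=[ProteinRecord(
                    protein_id=f"ref{i}", genome_id="ref", contig_id="r",
                    start=1, end=750, strand="+", sequence=seq,
                )],
            ))
        lineages = {}
        for lin in ("lin1", "lin2"):
            genes = []
            # plant homologs of fam0 and fam1 only
            for i in range(2):
                genes.append(ProteinRecord(
                    protein_id=f"{lin}.fam{i}", genome_id=lin, contig_id="c1",
                    start=1 + i * 1000, end=750 + i * 1000, strand="+",
                    sequence=mutate(seed_seqs[f"fam{i}"], 0.1, rng),
                ))
            for j in range(5):
                genes.append(ProteinRecord(
                    protein_id=f"{lin}.fill{j}", genome_id=lin,
                    contig_id="c1", start=1 + (j + 2) * 1000,
                    end=750 + (j + 2) * 1000, strand="+",
                    sequence=random_protein(rng, 250),
                ))
            lineages[lin] = [Genome(lin, contigs={"c1": genes})]
        retained, dropped = fm.build_enzyme_db(refs, lineages)
        assert {f.family_id for f in retained} == {"fam0", "fam1"}
        assert set(dropped) == {"fam2", "fam3", "fam4"}
        for fam in retained:
            assert len(fam.seeds) == 2  # one per lineage

    def test_empty_reference_rejected(self, bundle):
        with pytest.raises(ValueError):
            fm.build_enzyme_db([], {"lin": bundle.genomes[:1]})


class TestHeatMatrix:
    def test_cells_match_stats_flags(self, bundle, expanded):
        table = fm.copy_table(list(expanded.values()), bundle.genomes)
        stats = fm.expansion_stats(table)
        df = fm.heat_matrix(table, stats)
        by_fam = {s.family_id: s for s in stats}
        for fam in table.families:
            for g in table.genomes:
                cell = df.loc[fam, g]
                count = int(cell.rstrip("+*"))
                assert count == table.df.loc[fam, g]
                assert ("+" in cell) == (g in by_fam[fam].extra_copy_genomes)
                assert ("*" in cell) == (g in by_fam[fam].significant_genomes)

    def test_reorder_permutes_columns_only(self, bundle, expanded, tmp_path):
        table = fm.copy_table(list(expanded.values()), bundle.genomes)
        stats = fm.expansion_stats(table)
        order = table.genomes[::-1]
        df = fm.heat_matrix(table, stats, genome_order=order,
                            path=tmp_path / "h.tsv")
        base = fm.heat_matrix(table, stats)
        assert list(df.columns) == order
        assert df[order].equals(base[order])
        assert (tmp_path / "h.tsv").exists()


class TestExpansionVsGenomeSize:
    def test_totals_equal_column_sums(self, bundle, expanded):
        table = fm.copy_table(list(expanded.values()), bundle.genomes)
        df = fm.expansion_vs_genome_size(bundle.genomes, table)
        for g in bundle.genomes:
            assert df.loc[g.genome_id, "total_family_copies"] == \
                table.df[g.genome_id].sum()

    def test_monotone_planting_gives_positive_rank_correlation(self):
        # genomes built with copies added as gene count grows
        genomes = []
        counts = []
        for i in range(8):
            n_genes = 20 + 10 * i
            contig = [
                ProteinRecord(
                    protein_id=f"g{i}.p{j}", genome_id=f"g{i}",
                    contig_id="c1", start=1 + j * 1000, end=900 + j * 1000,
                    strand="+", sequence="MKVLAWWTYHG",
                )
                for j in range(n_genes)
            ]
            genomes.append(Genome(f"g{i}", contigs={"c1": contig}))
            counts.append(1 + i)
        table = _table({"f": counts}, [g.genome_id for g in genomes])
        df = fm.expansion_vs_genome_size(genomes, table)
        rho, _p = spearmanr(df["n_genes"], df["total_family_copies"])
        assert rho > 0.9
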