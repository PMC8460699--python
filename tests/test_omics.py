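"""Gene selection thresholds and the pathway activity score.

The pathway score is checked against an independent brute-force double
loop over patients and member genes, and by its algebraic symmetries.
"""

import numpy as np
import pandas as pd
import pytest

from wsimil.omics import (OmicsTable, PathwayDefinition, binarize_alterations,
                          make_label_table, pathway_activity, select_genes)


def brute_force_activity(table: OmicsTable, defs):
    """Independent evaluation: explicit loops, no vectorization."""
    out = {}
    for d in defs:
        col = []
        for patient in table.patients:
            total, n = 0.0, 0
            for gene, w in d.members:
                if gene in table.values.index:
                    u = table.values.at[gene, patient]
                    if not np.isnan(u):
                        total += w * u
                        n += 1
            col.append(total / n)
        out[d.pathway_id] = col
    return pd.DataFrame(out, index=table.patients)


def random_table(rng, genes, n_patients, kind="expression"):
    vals = rng.normal(0, 2, (len(genes), n_patients))
    cols = [f"P{i}" for i in range(n_patients)]
    return OmicsTable(pd.DataFrame(vals, index=genes, columns=cols), kind)


class TestSelectGenes:
    def _binary_table(self, counts, n_patients=100):
        rows = {}
        for gene, k in counts.items():
            row = np.zeros(n_patients, int)
            row[:k] = 1
            rows[gene] = row
        df = pd.DataFrame(rows).T
        df.columns = [f"P{i}" for i in range(n_patients)]
        return OmicsTable(df, "point_mutation")

    def test_at_least_rule_keeps_boundary(self):
        # point mutation rule: mutated in at least 3% of patients
        table = self._binary_table({"G3": 3})
        assert select_genes(table, 0.03, strict=False) == ["G3"]

    def test_strict_rule_drops_boundary(self):
        # CNA rule: altered in strictly more than 5%
        table = self._binary_table({"G5": 5, "G6": 6})
        assert select_genes(table, 0.05, strict=True) == ["G6"]

    def test_all_zero_gene_dropped(self):
        table = self._binary_table({"Z": 0, "A": 10})
        assert select_genes(table, 0.01) == ["A"]

    def test_sorted_by_prevalence_then_name(self):
        table = self._binary_table({"B": 10, "A": 10, "C": 20})
        assert select_genes(table, 0.05) == ["C", "A", "B"]

    def test_monotone_in_threshold(self, rng):
        table = self._binary_table(
            {f"G{i}": int(k) for i, k in enumerate(rng.integers(0, 30, 20))})
        lo = set(select_genes(table, 0.05))
        hi = set(select_genes(table, 0.15))
        assert hi <= lo


class TestBinarize:
    def test_cna_code_enumeration_default(self):
        df = pd.DataFrame({"P0": [-2], "P1": [-1], "P2": [0], "P3": [1], "P4": [2]},
                          index=["G"])
        out = binarize_alterations(OmicsTable(df, "cna"), "nonzero")
        assert out.values.loc["G"].tolist() == [1, 1, 0, 1, 1]

    def test_cna_code_enumeration_level2(self):
        df = pd.DataFrame({"P0": [-2], "P1": [-1], "P2": [0], "P3": [1], "P4": [2]},
                          index=["G"])
        out = binarize_alterations(OmicsTable(df, "cna"), "level2")
        assert out.values.loc["G"].tolist() == [1, 0, 0, 0, 1]

    def test_non_integer_cna_rejected(self):
        df = pd.DataFrame({"P0": [0.5]}, index=["G"])
        with pytest.raises(ValueError, match="integer"):
            binarize_alterations(OmicsTable(df, "cna"))


class TestPathwayActivity:
    def test_single_oncogene(self):
        t = OmicsTable(pd.DataFrame({"P0": [2.0]}, index=["MYC"]), "expression")
        act = pathway_activity(t, [PathwayDefinition("myc", [("MYC", 1)])])
        assert act.v.at["P0", "myc"] == 2.0
        assert act.l.at["P0", "myc"] == 1

    def test_single_suppressor_flips_sign(self):
        t = OmicsTable(pd.DataFrame({"P0": [2.0]}, index=["TP53"]), "expression")
        act = pathway_activity(t, [PathwayDefinition("p53", [("TP53", -1)])])
        assert act.v.at["P0", "p53"] == -2.0
        assert act.l.at["P0", "p53"] == 0

    def test_zero_activity_is_inactive(self):
        t = OmicsTable(pd.DataFrame({"P0": [0.0]}, index=["MYC"]), "expression")
        act = pathway_activity(t, [PathwayDefinition("myc", [("MYC", 1)])])
        assert act.l.at["P0", "myc"] == 0

    def test_hand_evaluated_mean(self):
        # (+1*3 + (-1)*1) / 2 = 1.0
        t = OmicsTable(pd.DataFrame({"P0": [3.0, 1.0]}, index=["ONC", "SUP"]),
                       "expression")
        act = pathway_activity(t, [PathwayDefinition("pw", [("ONC", 1), ("SUP", -1)])])
        assert act.v.at["P0", "pw"] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng, pathway_defs):
        genes = ["TP53", "MDM2", "RB1", "CCND1", "CDK4", "MYC"] + \
                [f"N{i}" for i in range(14)]
        table = random_table(rng, genes, 50)
        act = pathway_activity(table, pathway_defs)
        oracle = brute_force_activity(table, pathway_defs)
        np.testing.assert_allclose(act.v.to_numpy(), oracle.to_numpy(), atol=1e-9)
        np.testing.assert_array_equal(act.l.to_numpy(),
                                      (oracle.to_numpy() > 0).astype(int))

    def test_antisymmetry(self, rng, pathway_defs):
        genes = ["TP53", "MDM2", "RB1", "CCND1", "CDK4", "MYC"]
        table = random_table(rng, genes, 20)
        act = pathway_activity(table, pathway_defs)
        negated = OmicsTable(-table.values, "expression")
        act_neg = pathway_activity(negated, pathway_defs)
        np.testing.assert_allclose(act_neg.v.to_numpy(), -act.v.to_numpy())
        flipped = [PathwayDefinition(d.pathway_id, [(g, -w) for g, w in d.members])
                   for d in pathway_defs]
        act_both = pathway_activity(negated, flipped)
        np.testing.assert_allclose(act_both.v.to_numpy(), act.v.to_numpy())

    def test_missing_member_dropped_with_warning(self, rng):
        table = random_table(rng, ["MYC"], 5)
        defs = [PathwayDefinition("pw", [("MYC", 1), ("ABSENT", -1)])]
        with pytest.warns(UserWarning, match="ABSENT"):
            act = pathway_activity(table, defs)
        np.testing.assert_allclose(act.v["pw"].to_numpy(),
                                   table.values.loc["MYC"].to_numpy())

    def test_pathway_with_no_members_in_table_errors(self, rng):
        table = random_table(rng, ["MYC"], 5)
        with pytest.raises(ValueError, match="ghost"):
            pathway_activity(table, [PathwayDefinition("ghost", [("NOPE", 1)])])


class TestLabelTable:
    def test_empty_tasks(self):
        assert make_label_table([]).empty

    def test_pathway_column_is_passthrough(self, rng, pathway_defs):
        genes = ["TP53", "MDM2", "RB1", "CCND1", "CDK4", "MYC"]
        table = random_table(rng, genes, 30)
        act = pathway_activity(table, pathway_defs)
        out = make_label_table([("pathway-expr", "p53")], expr_activity=act)
        np.testing.assert_array_equal(out["p53_pathway-expr"].to_numpy(),
                                      act.l["p53"].to_numpy())

    def test_positive_count_in_binomial_band(self):
        from wsimil.synthetic import generate_omics
        om = generate_omics(1000, [("G", 0.05, "oncogene")], seed=3)
        out = make_label_table([("point", "G")], mutations=om.mutation_table)
        assert 30 <= out["G_point"].sum() <= 70

    def test_missing_cache_patient_warned(self, rng, pathway_defs):
        genes = ["TP53", "MDM2", "RB1", "CCND1", "CDK4", "MYC"]
        table = random_table(rng, genes, 5)
        act = pathway_activity(table, pathway_defs)
        with pytest.warns(UserWarning, match="P4"):
            make_label_table([("pathway-expr", "p53")], expr_activity=act,
                             known_patients=["P0", "P1", "P2", "P3"])
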