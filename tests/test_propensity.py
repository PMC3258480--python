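"""Propensity, role-profile and acting-part computations."""

import numpy as np
import pandas as pd
import pytest

from eck.propensity import (
    PropensityAnalyzer,
    acting_part_summary,
    background_composition,
    catalytic_composition,
    catalytic_propensity,
    role_profile,
)
from eck.records import AMINO_ACIDS, Dataset
from eck.synthetic import GeneratorConfig, generate

from conftest import build_record


class TestCompositions:
    def test_single_chain_all_alanine(self):
        ds = Dataset(records=[build_record(chains={"A": "AAAA"}, catalytic=[("A", 1)])])
        comp = background_composition(ds)
        assert comp["A"] == 1.0
        assert comp.drop("A").sum() == 0.0

    def test_two_chain_symmetry(self):
        ds = Dataset(
            records=[
                build_record(chains={"A": "AC", "B": "CA"}, catalytic=[("A", 1)])
            ]
        )
        comp = background_composition(ds)
        assert comp["A"] == pytest.approx(0.5)
        assert comp["C"] == pytest.approx(0.5)

    def test_background_sums_to_one_on_corpus(self, small_dataset):
        assert background_composition(small_dataset).sum() == pytest.approx(1.0, abs=1e-12)

    def test_catalytic_composition_counts_annotations(self):
        seq = "H" * 5 + "D" * 5 + "A" * 10
        ds = Dataset(
            records=[
                build_record(chains={"A": seq}, catalytic=[("A", 1), ("A", 2), ("A", 6)])
            ]
        )
        comp = catalytic_composition(ds)
        assert comp["H"] == pytest.approx(2 / 3)
        assert comp["D"] == pytest.approx(1 / 3)

    def test_binding_only_record_contributes_nothing_catalytic(self):
        binder = build_record(
            record_id="B",
            chains={"A": "ACDEF" * 4},
            binding=[("A", 1)],
            cofactors=[("MG", "metal_ion", ["stabilization"])],
        )
        catalytic = build_record(record_id="C", catalytic=[("A", 3)])
        comp = catalytic_composition(Dataset(records=[binder, catalytic]))
        assert comp.sum() == pytest.approx(1.0)
        assert comp["D"] == 1.0  # only the one catalytic Asp

    def test_empty_selection_is_an_error(self, small_dataset):
        with pytest.raises(ValueError):
            catalytic_composition(Dataset(records=[]))


def toy_corpus():
    """100 residues of which 10 His; 5 catalytic annotations, 2 of them His."""
    seq = "H" * 10 + "A" * 30 + "C" * 20 + "D" * 20 + "E" * 20
    record = build_record(
        chains={"A": seq},
        catalytic=[("A", 1), ("A", 2), ("A", 11), ("A", 41), ("A", 61)],
    )
    return Dataset(records=[record])


class TestPropensity:
    def test_hand_counted_his_propensity(self):
        table = catalytic_propensity(toy_corpus())
        # (2/5) / (10/100) = 4.0 under either reading of the ratio
        assert table.values.loc["H", "all"] == pytest.approx(4.0)

    def test_never_catalytic_type_scores_zero(self):
        table = catalytic_propensity(toy_corpus())
        assert table.values.loc["E", "all"] == 0.0
        assert ("E", "all") not in table.undefined

    def test_absent_type_flagged_not_zeroed(self):
        table = catalytic_propensity(toy_corpus())
        assert ("W", "all") in table.undefined
        assert np.isnan(table.values.loc["W", "all"])

    def test_uniform_corpus_gives_propensity_one(self):
        # catalytic composition == background composition => all defined cells 1
        ds = Dataset(
            records=[build_record(chains={"A": "HD"}, catalytic=[("A", 1), ("A", 2)])]
        )
        table = catalytic_propensity(ds)
        assert table.values.loc["H", "all"] == pytest.approx(1.0)
        assert table.values.loc["D", "all"] == pytest.approx(1.0)

    def test_weighted_mean_is_one(self, small_dataset):
        table = catalytic_propensity(small_dataset)
        table.check_weighted_mean(tol=1e-9)

    def test_duplicating_records_leaves_table_unchanged(self):
        ds = toy_corpus()
        doubled_records = [ds.records[0]] + [
            build_record(
                record_id="copy",
                chains={"A": ds.records[0].chains[0].sequence},
                catalytic=[("A", 1), ("A", 2), ("A", 11), ("A", 41), ("A", 61)],
            )
        ]
        doubled = Dataset(records=doubled_records)
        a = catalytic_propensity(ds).values
        b = catalytic_propensity(doubled).values
        pd.testing.assert_frame_equal(a, b)

    def test_multiplier_recovery_closed_form(self):
        """Planted multiplier m on a uniform background drives the estimated
        propensity to m / sum(bg * m) within 15% at 500 records."""
        cfg = GeneratorConfig(
            n_ec_nodes=100,
            families_per_node=[1] * 100,
            members_per_family=5,
            propensity_multipliers={"H": 4.0},
            rng_seed=0,
        )
        dataset, _ = generate(cfg)
        assert len(dataset) == 500
        table = catalytic_propensity(dataset)
        closed_form = 4.0 / (0.05 * 4.0 + 0.95)
        estimate = table.values.loc["H", "all"]
        assert abs(estimate / closed_form - 1.0) <= 0.15


class TestRoleProfile:
    def test_no_cofactors_means_zero_cofactor_rows(self):
        profile = role_profile(toy_corpus())
        assert profile.loc["metal_ion"].to_numpy().sum() == 0
        assert profile.loc["organic_cofactor"].to_numpy().sum() == 0

    def test_multi_role_annotation_counts_each_role(self):
        record = build_record(
            chains={"A": "H" + "A" * 19},
            catalytic=[("A", 1)],
            roles=("proton_shuttle", "stabilization"),
        )
        profile = role_profile(Dataset(records=[record]))
        assert profile.loc[("residue", "proton_shuttle"), 1] == 1
        assert profile.loc[("residue", "stabilization"), 1] == 1
        assert profile.loc["residue"][1].sum() == 2

    def test_hydride_shuttle_only_from_organic_cofactors(self, small_dataset):
        profile = role_profile(small_dataset)
        assert profile.loc[("residue", "hydride_shuttle"), "all"] == 0
        assert profile.loc[("metal_ion", "hydride_shuttle"), "all"] == 0


class TestActingParts:
    def test_all_side_chain(self):
        table = acting_part_summary(toy_corpus())
        assert (table["side_chain"] == 1.0).all()

    def test_main_chain_glycine(self):
        record = build_record(chains={"A": "G" + "A" * 19}, catalytic=[("A", 1)])
        ann = record.residue_annotations[0]
        object.__setattr__(ann, "acting_part", "main_chain_NH")
        table = acting_part_summary(Dataset(records=[record]))
        assert table.loc["G", "main_chain_NH"] == 1.0

    def test_fractions_sum_to_one(self, small_dataset):
        table = acting_part_summary(small_dataset)
        assert np.allclose(table.sum(axis=1), 1.0)


def test_analyzer_fit_and_sklearn_params(small_dataset):
    analyzer = PropensityAnalyzer()
    assert analyzer.get_params() == {"convention": "fraction_of_catalytic"}
    analyzer.fit(small_dataset)
    assert analyzer.transform(small_dataset).shape[0] == 20
    cloned = analyzer.set_params(convention="per_residue_rate")
    assert cloned.convention == "per_residue_rate"
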