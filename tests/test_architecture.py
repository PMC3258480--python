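"""Domain role labels, catalytic units, signatures, census, promiscuity."""

import pytest

from eck.architecture import (
    ArchitectureAnalyzer,
    architecture_signature,
    catalytic_unit,
    classify_domain_roles,
    configuration_census,
    domain_ec_promiscuity,
    single_domain_fraction,
    unassigned_catalytic_residues,
)
from eck.records import Dataset

from conftest import build_record

SEQ = "ACDEFGHIKLMNPQRSTVWY" * 3


class TestDomainRoles:
    @pytest.mark.parametrize(
        "catalytic, binding, expected",
        [
            ([("A", 5)], [], "catalytic"),  # >= 1 catalytic residue
            ([], [("A", 5), ("A", 6), ("A", 7)], "binding"),  # >= 3 binding
            ([], [("A", 5), ("A", 6)], "other"),  # below the binding threshold
        ],
    )
    def test_label_thresholds(self, catalytic, binding, expected):
        record = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 30)])],
            catalytic=catalytic,
            binding=binding,
            cofactors=[("MG", "metal_ion", ["stabilization"])],
        )
        labels = classify_domain_roles(record)
        assert [l.label for l in labels] == [expected]

    def test_every_domain_gets_exactly_one_label(self, small_dataset):
        for record in small_dataset:
            labels = classify_domain_roles(record)
            assert len(labels) == len(record.domains)

    def test_linker_catalytic_residue_reported_not_dropped(self):
        record = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 10)])],
            catalytic=[("A", 5), ("A", 40)],  # 40 lies outside the domain
        )
        labels = classify_domain_roles(record)
        assert labels[0].n_catalytic_residues == 1
        stray = unassigned_catalytic_residues(record)
        assert [a.position for a in stray] == [40]


class TestCatalyticUnit:
    def test_single_chain_single_domain(self):
        record = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 30)])],
            catalytic=[("A", 5)],
        )
        unit = catalytic_unit(record)
        assert unit.chains == ("A",)
        assert unit.derived is True

    def test_interface_site_spans_both_chains(self):
        # catalytic site at the interface between two chains, same domain code
        record = build_record(
            chains={"A": SEQ, "B": SEQ},
            domains=[
                ("A", "3.40.50.970", [(1, 30)]),
                ("B", "3.40.50.970", [(1, 30)]),
                ("B", "2.40.10.10", [(31, 60)]),
            ],
            catalytic=[("A", 5), ("B", 5)],
        )
        unit = catalytic_unit(record)
        assert unit.chains == ("A", "B")
        assert [d.cath_code for d in unit.domains] == ["3.40.50.970", "3.40.50.970"]

    def test_annotated_unit_overrides_derivation(self):
        record = build_record(
            chains={"A": SEQ, "B": SEQ},
            domains=[("A", "3.40.50.720", [(1, 30)]), ("B", "2.40.10.10", [(1, 30)])],
            catalytic=[("A", 5), ("B", 5)],
            catalytic_unit=["A"],
        )
        assert catalytic_unit(record).chains == ("A",)

    def test_no_catalytic_domain_and_no_annotation_flagged(self):
        record = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 10)])],
            catalytic=[("A", 40)],  # outside every domain
        )
        with pytest.raises(ValueError):
            catalytic_unit(record)


class TestSignatures:
    def test_single_catalytic_domain(self):
        record = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 30)])],
            catalytic=[("A", 5)],
        )
        sig = architecture_signature(record)
        assert (sig.pattern, sig.n_bio_domains) == ("A*", 1)

    def test_catalytic_plus_binding_domain(self):
        record = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 30)]), ("A", "1.10.600.10", [(31, 60)])],
            catalytic=[("A", 5)],
            binding=[("A", 35), ("A", 36), ("A", 37)],
        )
        sig = architecture_signature(record)
        assert (sig.pattern, sig.n_bio_domains) == ("A*B", 2)

    def test_non_catalytic_extra_domain_outside_unit(self):
        record = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 30)]), ("A", "1.10.600.10", [(31, 60)])],
            catalytic=[("A", 5)],
        )
        sig = architecture_signature(record)
        assert (sig.pattern, sig.n_bio_domains) == ("A*", 2)

    def test_duplicated_catalytic_domain(self):
        record = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.970", [(1, 30)]), ("A", "3.40.50.970", [(31, 60)])],
            catalytic=[("A", 5), ("A", 35)],
        )
        assert architecture_signature(record).pattern == "A*A*"

    def test_homodimer_biological_unit_counts_multiplicity(self):
        record = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 30)])],
            catalytic=[("A", 5)],
            biological_unit=["A", "A"],
        )
        assert architecture_signature(record).n_bio_domains == 2


class TestCensus:
    def test_empty_dataset_empty_census(self):
        assert configuration_census(Dataset(records=[])).empty

    def test_hand_counted_fixture(self):
        records = []
        for i in range(4):  # four A* single-domain enzymes
            records.append(
                build_record(
                    record_id=f"S{i}",
                    chains={"A": SEQ},
                    domains=[("A", "3.40.50.720", [(1, 30)])],
                    catalytic=[("A", 5)],
                )
            )
        for i in range(2):  # two A* with a second non-catalytic domain
            records.append(
                build_record(
                    record_id=f"T{i}",
                    chains={"A": SEQ},
                    domains=[
                        ("A", "3.40.50.720", [(1, 30)]),
                        ("A", "1.10.600.10", [(31, 60)]),
                    ],
                    catalytic=[("A", 5)],
                )
            )
        census = configuration_census(Dataset(records=records))
        as_dict = {
            (row["pattern"], row["n_bio_domains"]): row["count"]
            for _, row in census.iterrows()
        }
        assert as_dict == {("A*", 1): 4, ("A*", 2): 2}

    def test_census_total_equals_dataset_size(self, small_dataset):
        census = configuration_census(small_dataset)
        assert int(census["count"].sum()) == len(small_dataset)

    def test_single_domain_fraction_bounds(self):
        single = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 30)])],
            catalytic=[("A", 5)],
        )
        multi = build_record(
            record_id="R2",
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 30)]), ("A", "1.10.600.10", [(31, 60)])],
            catalytic=[("A", 5)],
        )
        assert single_domain_fraction(Dataset(records=[single])) == 1.0
        assert single_domain_fraction(Dataset(records=[multi])) == 0.0
        mixed = Dataset(records=[single, multi])
        assert single_domain_fraction(mixed) == 0.5


class TestPromiscuity:
    def make(self, record_id, ec, code="3.40.50.720"):
        return build_record(
            record_id=record_id,
            ec_nodes=(ec,),
            chains={"A": SEQ},
            domains=[("A", code, [(1, 30)])],
            catalytic=[("A", 5)],
        )

    def test_single_record_single_node(self):
        table = domain_ec_promiscuity(Dataset(records=[self.make("R1", "1.1.1.1")]))
        row = table.iloc[0]
        assert (row["ec_node_count"], row["ec_class_count"]) == (1, 1)

    def test_two_nodes_one_class(self):
        ds = Dataset(records=[self.make("R1", "1.1.1.1"), self.make("R2", "1.1.1.2")])
        row = domain_ec_promiscuity(ds).iloc[0]
        assert (row["ec_node_count"], row["ec_class_count"]) == (2, 1)

    def test_two_nodes_two_classes(self):
        ds = Dataset(records=[self.make("R1", "2.7.11.1"), self.make("R2", "3.4.21.4")])
        row = domain_ec_promiscuity(ds).iloc[0]
        assert (row["ec_node_count"], row["ec_class_count"]) == (2, 2)

    def test_class_count_never_exceeds_node_count(self, small_dataset):
        table = domain_ec_promiscuity(small_dataset)
        assert (table["ec_class_count"] <= table["ec_node_count"]).all()
        assert (table["ec_class_count"] >= 1).all()

    def test_non_catalytic_codes_excluded_by_default(self):
        record = build_record(
            chains={"A": SEQ},
            domains=[("A", "3.40.50.720", [(1, 30)]), ("A", "1.10.600.10", [(31, 60)])],
            catalytic=[("A", 5)],
        )
        ds = Dataset(records=[record])
        default = domain_ec_promiscuity(ds)
        widened = domain_ec_promiscuity(ds, catalytic_only=False)
        assert default["cath_code"].tolist() == ["3.40.50.720"]
        assert set(widened["cath_code"]) == {"3.40.50.720", "1.10.600.10"}


def test_analyzer_census_recovers_planted_architecture(small_synthetic):
    dataset, truth = small_synthetic
    analyzer = ArchitectureAnalyzer().fit(dataset)
    for record_id, sig in analyzer.signatures_.items():
        planted = truth.planted_architecture[record_id]
        assert sig.pattern == planted["pattern"]
        assert sig.n_bio_domains == planted["n_bio_domains"]
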