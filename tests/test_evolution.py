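import numpy as np
import pandas as pd
import pytest

from allclones.evolution import (
    calls_to_frame,
    classify_status,
    driver_gain_loss_summary,
    flag_rising,
    group_clones,
    relapse_associated_genes,
    rescue_low_af,
)
from allclones.io import mutations_to_frame


def paired_frame(rows):
    """rows: (pos, timepoint, af, alt, depth, called[, effect, gene])"""
    out = []
    for row in rows:
        pos, tp, af, alt, depth, called = row[:6]
        effect = row[6] if len(row) > 6 else "nsSNV"
        gene = row[7] if len(row) > 7 else "G1"
        out.append(
            dict(patient_id="P1", sample_id=f"P1-{tp}", timepoint=tp,
                 chrom="1", pos=pos, ref="C", alt="T", variant_class="SNV",
                 effect=effect, gene=gene, af=af, alt_reads=alt, depth=depth,
                 called=called)
        )
    return pd.DataFrame(out)


class TestClassifyStatus:
    def test_three_way_partition(self):
        rows = []
        # 3 diagnosis-only, 4 shared, 3 gained
        for i in range(3):
            rows.append((100 + i, "diagnosis", 0.3, 30, 100, True))
        for i in range(4):
            rows.append((200 + i, "diagnosis", 0.3, 30, 100, True))
            rows.append((200 + i, "relapse1", 0.3, 30, 100, True))
        for i in range(3):
            rows.append((300 + i, "relapse1", 0.3, 30, 100, True))
        calls = classify_status(paired_frame(rows))
        tally = pd.Series([c.status for c in calls]).value_counts()
        assert tally["diagnosis_only"] == 3
        assert tally["shared"] == 4
        assert tally["relapse_gained"] == 3

    def test_every_mutation_has_exactly_one_status(self):
        rows = [
            (1, "diagnosis", 0.3, 30, 100, True),
            (1, "relapse1", 0.3, 30, 100, True),
            (2, "relapse1", 0.2, 20, 100, True),
        ]
        calls = classify_status(paired_frame(rows))
        assert sorted(c.key[1] for c in calls) == [1, 2]

    def test_second_relapse_only_judged_against_first(self):
        rows = [
            (1, "diagnosis", 0.3, 30, 100, True),
            (1, "relapse1", 0.3, 30, 100, True),
            (5, "relapse2", 0.2, 20, 100, True),
        ]
        calls = {c.key[1]: c for c in classify_status(paired_frame(rows))}
        assert calls[5].status == "relapse_gained"
        assert calls[5].reference_timepoint == "relapse1"

    def test_single_timepoint_patient_rejected(self):
        rows = [(1, "diagnosis", 0.3, 30, 100, True)]
        with pytest.raises(ValueError, match="single timepoint"):
            classify_status(paired_frame(rows))


class TestRescue:
    def _gained_with_support(self, alt, depth):
        rows = [
            (1, "diagnosis", 0.4, 40, 100, True),
            (1, "relapse1", 0.4, 40, 100, True),
            (9, "relapse1", 0.3, 30, 100, True),
            (9, "diagnosis", alt / depth, alt, depth, False),
        ]
        return classify_status(paired_frame(rows))

    def test_low_af_support_rescues_gained_mutation(self):
        calls = rescue_low_af(self._gained_with_support(3, 600))
        gained = [c for c in calls if c.status == "relapse_gained"][0]
        assert gained.rescued_at_earlier_timepoint

    def test_zero_support_does_not_rescue(self):
        rows = [
            (1, "diagnosis", 0.4, 40, 100, True),
            (1, "relapse1", 0.4, 40, 100, True),
            (9, "relapse1", 0.3, 30, 100, True),
        ]
        calls = rescue_low_af(classify_status(paired_frame(rows)))
        gained = [c for c in calls if c.status == "relapse_gained"][0]
        assert not gained.rescued_at_earlier_timepoint

    def test_high_af_support_is_not_a_rescue(self):
        calls = rescue_low_af(self._gained_with_support(30, 600))
        gained = [c for c in calls if c.status == "relapse_gained"][0]
        assert not gained.rescued_at_earlier_timepoint  # af 0.05 >= 0.02

    def test_raising_min_alt_reads_never_increases_rescues(self):
        calls = self._gained_with_support(3, 600)
        low = sum(c.rescued_at_earlier_timepoint
                  for c in rescue_low_af(calls, min_alt_reads=2))
        high = sum(c.rescued_at_earlier_timepoint
                   for c in rescue_low_af(calls, min_alt_reads=5))
        assert high <= low

    def test_residual_support_at_relapse_flagged(self):
        rows = [
            (1, "diagnosis", 0.4, 40, 100, True),
            (1, "relapse1", 0.4, 40, 100, True),
            (7, "diagnosis", 0.3, 30, 100, True),
            (7, "relapse1", 0.005, 3, 600, False),
        ]
        calls = rescue_low_af(classify_status(paired_frame(rows)))
        dia_only = [c for c in calls if c.status == "diagnosis_only"][0]
        assert dia_only.residual_at_relapse


class TestRising:
    @pytest.mark.parametrize(
        "af_dia,af_rel,expected",
        [(0.10, 0.25, True), (0.20, 0.40, True), (0.30, 0.30, False)],
    )
    def test_doubling_rule_boundary_inclusive(self, af_dia, af_rel, expected):
        rows = [
            (1, "diagnosis", af_dia, int(af_dia * 1000), 1000, True),
            (1, "relapse1", af_rel, int(af_rel * 1000), 1000, True),
            (2, "diagnosis", 0.4, 400, 1000, True),
            (2, "relapse1", 0.4, 400, 1000, True),
        ]
        calls = flag_rising(classify_status(paired_frame(rows)))
        target = [c for c in calls if c.key[1] == 1][0]
        assert target.rising is expected

    def test_gained_mutations_not_marked_rising(self):
        rows = [
            (1, "diagnosis", 0.4, 40, 100, True),
            (1, "relapse1", 0.4, 40, 100, True),
            (9, "relapse1", 0.3, 30, 100, True),
        ]
        calls = flag_rising(classify_status(paired_frame(rows)))
        gained = [c for c in calls if c.status == "relapse_gained"][0]
        assert not gained.rising


class TestCloneGrouping:
    def test_similar_trajectories_grouped(self):
        rows = [
            (1, "diagnosis", 0.40, 40, 100, True),
            (1, "relapse1", 0.41, 41, 100, True),
            (2, "diagnosis", 0.42, 42, 100, True),
            (2, "relapse1", 0.40, 40, 100, True),
            (3, "diagnosis", 0.10, 10, 100, True),
            (3, "relapse1", 0.11, 11, 100, True),
        ]
        clones = group_clones(classify_status(paired_frame(rows)), 0.05)
        sizes = sorted(len(c.member_keys) for c in clones)
        assert sizes == [1, 2]

    def test_diagnosis_only_clone_is_eradicated(self):
        rows = [
            (1, "diagnosis", 0.4, 40, 100, True),
            (1, "relapse1", 0.4, 40, 100, True),
            (5, "diagnosis", 0.2, 20, 100, True),
        ]
        clones = group_clones(classify_status(paired_frame(rows)))
        fates = {tuple(c.member_keys[0])[1]: c.fate for c in clones}
        assert fates[5] == "eradicated"

    def test_planted_two_clone_structure_recovered_under_noise(self):
        rng = np.random.default_rng(8)
        rows = []
        for i, (d, r) in enumerate([(0.45, 0.44), (0.45, 0.45)]):
            rows.append((10 + i, "diagnosis", d + rng.normal(0, 0.01), 40, 100, True))
            rows.append((10 + i, "relapse1", r + rng.normal(0, 0.01), 40, 100, True))
        for i, (d, r) in enumerate([(0.10, 0.30), (0.10, 0.31)]):
            rows.append((20 + i, "diagnosis", d + rng.normal(0, 0.01), 10, 100, True))
            rows.append((20 + i, "relapse1", r + rng.normal(0, 0.01), 30, 100, True))
        frame = paired_frame(
            [(p, tp, round(min(max(af, 0.01), 0.99), 3),
              int(round(min(max(af, 0.01), 0.99) * 100)), 100, c)
             for p, tp, af, _, _, c in rows]
        )
        clones = group_clones(classify_status(frame), af_tolerance=0.05)
        groups = sorted(sorted(k[1] for k in c.member_keys) for c in clones)
        assert groups == [[10, 11], [20, 21]]

    def test_order_invariance(self):
        rows = [
            (1, "diagnosis", 0.4, 40, 100, True),
            (1, "relapse1", 0.4, 40, 100, True),
            (5, "diagnosis", 0.2, 20, 100, True),
            (5, "relapse1", 0.5, 50, 100, True),
        ]
        a = group_clones(classify_status(paired_frame(rows)))
        b = group_clones(classify_status(paired_frame(rows[::-1])))
        assert [sorted(c.member_keys) for c in a] == [sorted(c.member_keys) for c in b]


def patients_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "immunophenotype", "outcome"]
    ).assign(subtype="HeH", age_years=5.0, time_to_event_years=5.0)


class TestRelapseGenes:
    def _calls(self, spec_rows):
        """spec_rows: (patient, gene, status)"""
        frame_rows = []
        for i, (pid, gene, status) in enumerate(spec_rows):
            if status in ("shared", "diagnosis_only"):
                frame_rows.append(
                    dict(patient_id=pid, sample_id=pid, timepoint="diagnosis",
                         chrom="1", pos=10 + i, ref="C", alt="T",
                         variant_class="SNV", effect="nsSNV", gene=gene,
                         af=0.3, alt_reads=30, depth=100, called=True)
                )
            if status in ("shared", "relapse_gained"):
                frame_rows.append(
                    dict(patient_id=pid, sample_id=pid, timepoint="relapse1",
                         chrom="1", pos=10 + i, ref="C", alt="T",
                         variant_class="SNV", effect="nsSNV", gene=gene,
                         af=0.3, alt_reads=30, depth=100, called=True)
                )
            # anchor second timepoint so every patient is paired
            frame_rows.append(
                dict(patient_id=pid, sample_id=pid, timepoint="relapse1",
                     chrom="2", pos=900 + i, ref="C", alt="T",
                     variant_class="SNV", effect="silent", gene="ANCHOR",
                     af=0.3, alt_reads=30, depth=100, called=True)
            )
            frame_rows.append(
                dict(patient_id=pid, sample_id=pid, timepoint="diagnosis",
                     chrom="2", pos=900 + i, ref="C", alt="T",
                     variant_class="SNV", effect="silent", gene="ANCHOR",
                     af=0.3, alt_reads=30, depth=100, called=True)
            )
        return classify_status(pd.DataFrame(frame_rows))

    def test_two_gained_mutations_satisfy_criterion_one(self):
        calls = self._calls([("P1", "EP300", "relapse_gained"),
                             ("P2", "EP300", "relapse_gained")])
        pats = patients_frame([("P1", "BCP", "relapse"), ("P2", "BCP", "relapse")])
        out = relapse_associated_genes(calls, pd.DataFrame(
            columns=["patient_id", "timepoint", "called", "effect", "gene"]), pats)
        row = out.set_index("gene").loc["EP300"]
        assert row["criterion1"] and row["flagged"]

    def test_gained_plus_relapsed_diagnostic_carrier_satisfies_criterion_two(self):
        calls = self._calls([("P1", "EP300", "relapse_gained")])
        dia = pd.DataFrame(
            [dict(patient_id="P3", timepoint="diagnosis", called=True,
                  effect="nsSNV", gene="EP300")]
        )
        pats = patients_frame(
            [("P1", "BCP", "relapse"), ("P3", "BCP", "relapse")]
        )
        out = relapse_associated_genes(calls, dia, pats)
        row = out.set_index("gene").loc["EP300"]
        assert not row["criterion1"] and row["criterion2"] and row["flagged"]

    def test_cr1_carrier_of_same_immunophenotype_voids_criterion_two(self):
        calls = self._calls([("P1", "EP300", "relapse_gained")])
        dia = pd.DataFrame(
            [
                dict(patient_id="P3", timepoint="diagnosis", called=True,
                     effect="nsSNV", gene="EP300"),
                dict(patient_id="P4", timepoint="diagnosis", called=True,
                     effect="nsSNV", gene="EP300"),
            ]
        )
        pats = patients_frame(
            [("P1", "BCP", "relapse"), ("P3", "BCP", "relapse"),
             ("P4", "BCP", "CR1")]
        )
        out = relapse_associated_genes(calls, dia, pats)
        assert not out.set_index("gene").loc["EP300", "flagged"]

    def test_cr1_carrier_of_other_immunophenotype_does_not_void(self):
        calls = self._calls([("P1", "EP300", "relapse_gained")])
        dia = pd.DataFrame(
            [
                dict(patient_id="P3", timepoint="diagnosis", called=True,
                     effect="nsSNV", gene="EP300"),
                dict(patient_id="P5", timepoint="diagnosis", called=True,
                     effect="nsSNV", gene="EP300"),
            ]
        )
        pats = pd.DataFrame(
            {
                "patient_id": ["P1", "P3", "P5"],
                "immunophenotype": ["BCP", "BCP", "T"],
                "outcome": ["relapse", "relapse", "CR1"],
            }
        )
        out = relapse_associated_genes(calls, dia, pats)
        assert bool(out.set_index("gene").loc["EP300", "criterion2"])


class TestGainLossSummary:
    def test_tally_by_status(self):
        rows = [
            (1, "diagnosis", 0.3, 30, 100, True, "nsSNV", "KRAS"),
            (2, "diagnosis", 0.3, 30, 100, True, "nsSNV", "KRAS"),
            (3, "diagnosis", 0.3, 30, 100, True, "nsSNV", "KRAS"),
            (3, "relapse1", 0.3, 30, 100, True, "nsSNV", "KRAS"),
        ]
        calls = classify_status(paired_frame(rows))
        out = driver_gain_loss_summary(calls, ["KRAS"])
        assert out.loc["KRAS", "lost"] == 2 and out.loc["KRAS", "gained"] == 0

    def test_empty_paired_set_all_zero(self):
        out = driver_gain_loss_summary([], ["KRAS", "NRAS"])
        assert (out[["lost", "gained"]] == 0).all().all()

    def test_planted_ras_dynamics_recovered(self):
        # plant 9 non-silent diagnostic Ras mutations, 7 lost at relapse,
        # and 6 relapse-gained ones, spread over Ras genes
        rows = []
        ras = ["KRAS", "NRAS", "PTPN11", "FLT3"]
        for i in range(9):
            rows.append((100 + i, "diagnosis", 0.3, 30, 100, True, "nsSNV",
                         ras[i % 4]))
            if i >= 7:  # two survive at relapse
                rows.append((100 + i, "relapse1", 0.3, 30, 100, True, "nsSNV",
                             ras[i % 4]))
        for i in range(6):
            rows.append((200 + i, "relapse1", 0.3, 30, 100, True, "nsSNV",
                         ras[i % 4]))
        calls = classify_status(paired_frame(rows))
        out = driver_gain_loss_summary(calls, ras)
        assert out["lost"].sum() == 7 and out["gained"].sum() == 6


class TestTruthRecovery:
    def test_noise_free_pairs_reproduce_truth_exactly(self, noise_free_pairs):
        muts, _, truth, _ = noise_free_pairs
        frame = mutations_to_frame(muts)
        paired_ids = set(
            frame.loc[frame["timepoint"].isin(("relapse1", "relapse2")),
                      "patient_id"]
        )
        calls = flag_rising(rescue_low_af(classify_status(
            frame[frame["patient_id"].isin(paired_ids)]
        )))
        got = calls_to_frame(calls).set_index(["patient_id", "chrom", "pos"])
        want = truth.pairs.set_index(["patient_id", "chrom", "pos"])
        joined = want.join(got, rsuffix="_called")
        assert len(joined) == len(want)
        for col in ("status", "rescued", "residual", "rising"):
            assert (joined[col] == joined[f"{col}_called"]).all(), col
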