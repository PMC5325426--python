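import numpy as np
import pandas as pd
import pytest

from allclones.io import MutationRecord
from allclones.simulate import SimConfig, simulate_cohort, simulate_relapse_pairs


def make_record(**overrides) -> MutationRecord:
    base = dict(
        patient_id="P1",
        sample_id="P1-dx",
        timepoint="diagnosis",
        chrom="1",
        pos=1000,
        ref="C",
        alt="T",
        variant_class="SNV",
        effect="nsSNV",
        gene="KRAS",
        af=0.30,
        alt_reads=30,
        depth=100,
        called=True,
    )
    base.update(overrides)
    return MutationRecord(**base)


@pytest.fixture(scope="session")
def default_cohort():
    cfg = SimConfig(seed=3)
    return simulate_cohort(cfg) + (cfg,)


@pytest.fixture(scope="session")
def noise_free_pairs():
    cfg = SimConfig(seed=5, noise_free=True)
    mutations, patients, truth = simulate_cohort(cfg)
    mutations, truth = simulate_relapse_pairs(mutations, patients, truth, cfg)
    return mutations, patients, truth, cfg


def screen_cohort(seed: int, hazard_ratio: float = 3.0, n: int = 300,
                  n_mutated: int = 60):
    """Pathway-screen benchmark: one hazard pathway plus background pathways."""
    from allclones.simulate import simulate_outcomes

    out = simulate_outcomes(n, n_mutated, hazard_ratio, seed=seed)
    rng = np.random.default_rng(seed + 99)
    outcome = np.where(
        out["event"] == "relapse", "relapse",
        np.where(out["event"] == "censored", "CR1", "DCR1"),
    )
    patients = pd.DataFrame(
        {
            "patient_id": out["patient_id"], "immunophenotype": "BCP",
            "subtype": "HeH", "age_years": 5.0, "sex": "F",
            "blast_fraction": 0.9, "outcome": outcome,
            "time_to_event_years": out["time"], "cohort": "core",
        }
    )
    pw_rows = [{"gene": "CREBBP", "pathway_id": "Notch", "pathway_name": "Notch"}]
    for i in range(8):
        pw_rows.append(
            {"gene": f"G{i}", "pathway_id": f"PW{i}", "pathway_name": f"PW{i}"}
        )
    rows = []
    for pid, mutated in zip(out["patient_id"], out["mutated"]):
        if mutated:
            rows.append(
                dict(patient_id=pid, sample_id=pid, timepoint="diagnosis",
                     chrom="16", pos=int(rng.integers(1, 100000)), ref="C",
                     alt="T", variant_class="SNV", effect="nsSNV", gene="CREBBP",
                     af=0.4, alt_reads=40, depth=100, called=True)
            )
        if rng.random() < 0.3:
            rows.append(
                dict(patient_id=pid, sample_id=pid, timepoint="diagnosis",
                     chrom="1", pos=int(rng.integers(1, 100000)), ref="C",
                     alt="T", variant_class="SNV", effect="nsSNV",
                     gene=f"G{rng.integers(8)}",
                     af=0.4, alt_reads=40, depth=100, called=True)
            )
    return pd.DataFrame(rows), patients, pd.DataFrame(pw_rows)
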