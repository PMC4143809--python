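import numpy as np
import pytest

from dirigwas import simulate, states, transition


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded ~250-subject cohort with one strong causal SNP."""
    cfg = simulate.SimulationConfig(n_families=50, n_markers=40, seed=123,
                                    causal_effects={0: 1.2},
                                    clinical_missing_rate=0.01)
    geno, fam_ids, records, truth = simulate.simulate_cohort(cfg)
    return {"cfg": cfg, "genotypes": geno, "family_ids": fam_ids,
            "records": records, "truth": truth}


@pytest.fixture(scope="session")
def cohort_responses(small_cohort):
    """State sequences, transition fits and simplex responses for the cohort."""
    seqs = states.build_state_sequences(small_cohort["records"])
    rows = transition.build_transition_rows(seqs)
    fits = transition.fit_transition_models(
        rows, select_time=False, formulas={1: "base", 2: "base", 3: "base"})
    responses = transition.responses_to_frame(
        [transition.extract_response(s, fits) for s in seqs])
    return {"sequences": seqs, "rows": rows, "fits": fits,
            "responses": responses}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
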