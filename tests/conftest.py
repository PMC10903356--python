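import pandas as pd
import pytest
from hypothesis import settings

import tici

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_survey():
    """20 sites x 6 replicates x 400 ASVs, strong gradient."""
    cfg = tici.SyntheticConfig(n_sites=20, replicates_per_site=6, n_asvs=400,
                               frac_informative=0.5, seed=1)
    return tici.generate_survey(cfg)


@pytest.fixture(scope="session")
def large_survey():
    """40 sites x 16 replicates x 2000 ASVs, 50% informative, strong gradient."""
    cfg = tici.SyntheticConfig(n_sites=40, replicates_per_site=16,
                               n_asvs=2000, frac_informative=0.5, seed=11)
    return tici.generate_survey(cfg)


@pytest.fixture(scope="session")
def small_model(small_survey):
    """Trained + oriented model on the small survey, with its trace."""
    table, design, _ = small_survey
    pm = tici.presence_matrix(table)
    indicators = tici.select_indicators(pm, design, 200)
    init = tici.random_init(sorted(design.site_ids), seed=1)
    model, trace = tici.chessman_train(pm, design, indicators, init)
    oriented = tici.orient_model(model, trace.final_site_scores,
                                 design.reference_scores())
    return oriented, model, trace


def make_monotone_fixture(n_sites=7, reps=6):
    """Noiseless survey whose ASV prevalences are strictly monotone in a
    known site ordering: positive ASVs appear in i of site i's replicates,
    negative ASVs in (n_sites-1-i). Returns (table, design, site order)."""
    sites = [f"S{i}" for i in range(n_sites)]
    rows = []
    samples = {}
    for i, site in enumerate(sites):
        for r in range(reps):
            sample = f"{site}_r{r}"
            samples[sample] = (site, "field_sample")
            present = []
            if r < i:
                present += ["posA", "posB"]
            if r < (n_sites - 1 - i):
                present += ["negA", "negB"]
            if r == 0:
                present += ["ubiq"]  # constant ASV, should score 5
            for asv in present:
                rows.append({"sample_id": sample, "asv_id": asv,
                             "assay": "CI", "count": 10})
    table = tici.ASVTable.from_records(pd.DataFrame(rows))
    design = tici.SiteDesign(samples=samples)
    return table, design, sites
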