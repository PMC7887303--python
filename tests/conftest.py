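import pytest

from ghdrule.synthetic import default_specs, simulate_cohort

# Published per-predictor 2x2 counts of the derivation cohort
# (a = predictor+ cases, b = predictor+ controls, c/d their complements),
# with the printed odds ratio.  Pituitary dysgenesis is tabulated on the
# MRI-assessed subset.
TABLE3 = {
    "pituitary_dysgenesis": (38, 0, 82, 98, float("inf")),
    "midline_abnormality": (19, 17, 131, 603, 5.1),
    "sellar_tumor_surgery": (13, 3, 137, 617, 19.5),
    "cns_infection": (0, 6, 150, 614, 0.0),
    "severe_tbi": (1, 2, 149, 618, 2.1),
    "cranial_radiotherapy_ge18Gy": (10, 10, 140, 610, 4.4),
    "chemotherapy_ge6mo": (10, 11, 140, 609, 4.0),
    "genetic_ghd": (3, 1, 147, 619, 12.6),
    "tsh_deficiency": (42, 1, 108, 619, 240.7),
    "acth_deficiency": (32, 0, 118, 620, float("inf")),
    "prolactin_deficiency": (3, 0, 147, 620, float("inf")),
    "central_diabetes_insipidus": (17, 4, 133, 616, 19.7),
    "neonatal_hypoglycemia": (18, 12, 132, 608, 6.9),
    "neonatal_cholestasis": (5, 4, 145, 616, 5.3),
    "neonatal_hypogenitalism": (18, 8, 132, 612, 10.4),
}


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture(scope="session")
def derivation_cohort(specs):
    return simulate_cohort(specs["derivation_2004_2014"], seed=7)


@pytest.fixture(scope="session")
def validation_cohort(specs):
    return simulate_cohort(specs["validation_2017_2019"], seed=7)
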