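import pytest

import dietlp as d


@pytest.fixture(scope="session")
def toy2():
    """toy2 fixture bundle: foods, intakes, profile, categories, base
    constraint set (energy equality only) and the observed pattern."""
    foods, intakes, profile = d.make_toy_fixture("toy2")
    cats = d.aggregate_categories(intakes, foods, profile.group)
    cs = d.build_constraint_set(profile)
    obs = d.observed_pattern(intakes, cats, profile.group)
    return foods, intakes, profile, cats, cs, obs


@pytest.fixture(scope="session")
def toy3():
    foods, intakes, profile = d.make_toy_fixture("toy3")
    cats = d.aggregate_categories(intakes, foods, profile.group)
    cs = d.build_constraint_set(profile)
    obs = d.observed_pattern(intakes, cats, profile.group)
    return foods, intakes, profile, cats, cs, obs


@pytest.fixture(scope="session")
def synth():
    """Small seeded synthetic survey shared by the unit tests."""
    spec = d.TaxonomySpec(n_categories=60)
    foods = d.generate_food_database(n_foods=150, taxonomy_spec=spec, seed=3)
    intakes, profiles = d.generate_intake_survey(
        foods, dict.fromkeys(d.SEX_AGE_GROUPS, 40), seed=3)
    return foods, intakes, profiles


@pytest.fixture(scope="session")
def synth_filtered(synth):
    foods, intakes, profiles = synth
    return (d.filter_foods(foods), d.filter_individuals(intakes, foods),
            profiles)


@pytest.fixture(scope="session")
def synth_group(synth_filtered):
    """One aggregated synthetic group ready for LP work."""
    foods_f, intakes_f, profiles = synth_filtered
    group = "F31-50"
    cats = d.aggregate_categories(intakes_f, foods_f, group)
    bounds = d.consumption_percentiles(intakes_f, foods_f, group)
    profile = next(p for p in profiles if p.group == group)
    cs = d.build_constraint_set(profile, bounds)
    obs = d.observed_pattern(intakes_f, cats, group)
    return cats, bounds, profile, cs, obs
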