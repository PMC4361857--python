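import numpy as np
import pytest
from hypothesis import settings

from isodiet import (IsotopeVector, Region, AgeClass, SourceGroup, SourceSample,
                     SpecimenRecord)

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def specimen():
    return SpecimenRecord(
        specimen_id="s1", region=Region.EASTERN, site="siteA",
        year_lo=1900, year_hi=1910, age_class=AgeClass.ADULT, age_years=8.0,
        isotopes=IsotopeVector(d13C=-19.5, d15N=8.2, d34S=9.1),
        pct_C=43.0, pct_N=15.5, pct_S=0.25,
    )


def make_specimen(i=0, *, d13C=-19.5, d15N=8.0, d34S=9.0, pct_C=43.0,
                  pct_N=15.5, pct_S=0.25, age_years=8.0,
                  age_class=AgeClass.ADULT, region="eastern",
                  year_lo=2000.0, year_hi=2000.0, site="s"):
    return SpecimenRecord(
        specimen_id=f"sp{i}", region=Region(region), site=site,
        year_lo=year_lo, year_hi=year_hi, age_class=age_class,
        age_years=age_years,
        isotopes=IsotopeVector(d13C=d13C, d15N=d15N, d34S=d34S),
        pct_C=pct_C, pct_N=pct_N, pct_S=pct_S,
    )


def make_source_group(name, mu13, mu15, mu34, omega=0.5, q=(0.45, 0.1, 0.005), n=10):
    return SourceGroup(
        name=name,
        mu={"d13C": mu13, "d15N": mu15, "d34S": mu34},
        omega={"d13C": omega, "d15N": omega, "d34S": omega},
        q={"d13C": q[0], "d15N": q[1], "d34S": q[2]},
        n=n,
    )


@pytest.fixture
def source_samples():
    """Three well-separated categories, 6 samples each, deterministic."""
    rng = np.random.default_rng(7)
    out = []
    means = {"alpha": (-30.0, 1.0, 2.0), "beta": (-20.0, 8.0, 10.0),
             "gamma": (-12.0, 15.0, 18.0)}
    for cat, (c, n, s) in means.items():
        for i in range(6):
            out.append(SourceSample(
                sample_id=f"{cat}{i}", category=cat, region=Region.EASTERN,
                isotopes=IsotopeVector(
                    d13C=c + rng.normal(0, 0.3),
                    d15N=n + rng.normal(0, 0.3),
                    d34S=s + rng.normal(0, 0.3)),
                pct_C=45.0, pct_N=5.0, pct_S=0.5))
    return out
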