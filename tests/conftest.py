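import numpy as np
import pandas as pd
import pytest

from hdss import SimulationConfig, generate, from_dataframe


@pytest.fixture(scope="session")
def bundle():
    """One mid-size generated census bundle shared across module tests."""
    return generate(SimulationConfig(seed=11, n_households=1500))


@pytest.fixture(scope="session")
def clean_bundle():
    """Bundle with no reporting errors: no heaping, no omission, full coverage."""
    return generate(
        SimulationConfig(
            seed=11,
            n_households=1500,
            heaping_prob=0.0,
            death_omission_prob={0: 0.0},
            iddir_coverage=1.0,
        )
    )


def make_census_df(rows):
    """Minimal persons table from (person_id, household_id, age, sex) tuples."""
    df = pd.DataFrame(rows, columns=["person_id", "household_id", "age", "sex"])
    df["residence"] = "rural"
    df["education"] = "primary"
    df["religion"] = "protestant"
    df["ethnicity"] = "sidama"
    df["marital_status"] = "married"
    df["gave_birth_last_year"] = False
    return df


@pytest.fixture
def tiny_dataset():
    rows = [(i, i // 3, age, sex) for i, (age, sex) in enumerate(
        [(0, "male"), (4, "female"), (5, "male"), (12, "female"), (25, "male"),
         (30, "female"), (47, "female"), (62, "male"), (70, "female"), (88, "male")]
    )]
    return from_dataframe(make_census_df(rows))


# --- published fertility-determinants cross-tab, reconstructed as microdata ---

CROSSTAB_AGE = {  # band -> (gave birth, did not); the 20-24 "no" cell is the
    # reconciled 1,147 (prints as 147, inconsistent with the 6,628 total)
    "15-19": (44, 1713),
    "20-24": (167, 1147),
    "25-29": (166, 994),
    "30-34": (97, 654),
    "35-39": (72, 676),
    "40-44": (24, 508),
    "45-49": (3, 363),
}

CROSSTAB_RESIDENCE = {"rural": (436, 4970), "urban": (137, 1085)}

CROSSTAB_EDUCATION = {
    "illiterate_read_write": (191, 1806),
    "basic": (107, 1608),
    "primary": (170, 1726),
    "secondary": (79, 778),
    "higher": (26, 137),
}


def microdata_from_counts(counts: dict, column: str) -> "pd.DataFrame":
    """Expand {level: (yes, no)} into per-woman census rows (ages in-band)."""
    frames = []
    pid = 0
    for level, (yes, no) in counts.items():
        n = yes + no
        if column == "age_group":
            age = int(level.split("-")[0]) + 2  # any in-band age
            extra = {}
        else:
            age = 30
            extra = {column: level}
        df = make_census_df(
            [(pid + i, pid + i, age, "female") for i in range(n)]
        )
        for k, v in extra.items():
            df[k] = v
        df["gave_birth_last_year"] = [True] * yes + [False] * no
        frames.append(df)
        pid += n
    return pd.concat(frames, ignore_index=True)
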