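import numpy as np
import pytest
from hypothesis import settings

from premnlp.corpus import FrequencyLexicon, SurveySchema

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def schema():
    return SurveySchema.from_ids(["Q1", "Q2", "Q3", "Q4", "Q5"])


@pytest.fixture
def small_lexicon():
    return FrequencyLexicon(
        {
            "goed": 120,
            "goede": 40,
            "informatie": 30,
            "wachten": 25,
            "lang": 20,
            "hello": 10,
            "help": 5,
            "arts": 15,
            "vriendelijk": 12,
            "duidelijk": 9,
        }
    )


def levenshtein(a: str, b: str) -> int:
    """Plain DP edit distance (with transposition counted as one edit,
    Damerau-style, matching the corrector's edit set)."""
    la, lb = len(a), len(b)
    d = np.zeros((la + 1, lb + 1), dtype=int)
    d[:, 0] = np.arange(la + 1)
    d[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = int(a[i - 1] != b[j - 1])
            d[i, j] = min(d[i - 1, j] + 1, d[i, j - 1] + 1, d[i - 1, j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i, j] = min(d[i, j], d[i - 2, j - 2] + 1)
    return int(d[la, lb])


@pytest.fixture
def edit_distance():
    return levenshtein
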