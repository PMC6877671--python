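import pytest
from hypothesis import HealthCheck, settings as _hyp_settings

_hyp_settings.register_profile(
    "episelect", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
_hyp_settings.load_profile("episelect")

from episelect.binding import AlleleScoreMatrix, MatrixRegistry
from episelect.core import PatientHLA


@pytest.fixture
def toy_matrix():
    """The 3-position hand-checkable matrix used across scoring tests.

    max score = 10 + 8 + 6 = 24; peptide ALK scores 24 (100%), GAK scores
    8 (33.3%).
    """
    return AlleleScoreMatrix(
        allele="A*01", length=3,
        weights={1: {"A": 10, "G": 0}, 2: {"L": 8, "A": 2}, 3: {"K": 6, "Y": 6}})


@pytest.fixture
def toy_registry(toy_matrix):
    return MatrixRegistry([toy_matrix])


@pytest.fixture
def toy_patient():
    return PatientHLA("P1", ("A*01",))


def write_tsv(path, header, rows):
    lines = ["\t".join(header)]
    lines += ["\t".join(str(c) for c in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
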