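import logging

import numpy as np
import pytest

from vvdyn.cohort import Cohort, SubjectSeries

logging.getLogger("vvdyn").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_subject(subject_id="s1", group="ms", vv=None, time_unit="months", **extra):
    vv = np.asarray(vv if vv is not None else [100.0, 101.0, 99.0], dtype=float)
    variables = {"ventricle_volume": vv}
    variables.update({k: np.asarray(v, dtype=float) for k, v in extra.items()})
    return SubjectSeries(
        subject_id=subject_id,
        group=group,
        time=np.arange(len(vv), dtype=float),
        time_unit=time_unit,
        variables=variables,
    )


@pytest.fixture
def tiny_cohort():
    return Cohort(
        subjects=[
            make_subject("a", vv=[100, 104, 101]),
            make_subject("b", vv=[200, 196, 202]),
        ]
    )
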