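import numpy as np
import pytest
from hypothesis import strategies as st

import fermkit as fk
from fermkit.identifiers import Environment, Media, Strain, TrialIdentifier

# -- hypothesis strategies ---------------------------------------------------

_name = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), whitelist_characters="-_."),
    min_size=1, max_size=8,
)
_finite = st.floats(min_value=0.0, max_value=1e6, allow_nan=False, allow_infinity=False)


@st.composite
def identifiers(draw, with_analyte=True):
    """Random valid TrialIdentifier covering every grammar field."""
    strain = Strain(
        name=draw(_name),
        knockouts=tuple(draw(st.lists(_name, max_size=2, unique=True))),
        plasmids=tuple(draw(st.lists(_name, max_size=2, unique=True))),
    )
    # component names are identifier *keys*, hence case-insensitive: draw lowercase
    _comp_name = st.text(alphabet="abcdefghij-_", min_size=1, max_size=8)
    components = tuple(
        (n, draw(_finite), draw(st.sampled_from(["g/L", "mM", ""])))
        for n in draw(st.lists(_comp_name, max_size=2, unique=True))
    )
    media = Media(name=draw(_name), components=components)
    env = Environment(
        labware=draw(st.sampled_from(["", "flask", "96-well-plate"])),
        temperature=draw(st.none() | st.floats(min_value=4, max_value=60, allow_nan=False)),
        shaking_speed=draw(st.none() | st.floats(min_value=0, max_value=500, allow_nan=False)),
    )
    return TrialIdentifier(
        strain=strain, media=media, environment=env,
        experiment_label=draw(st.sampled_from(["", "exp1"])),
        replicate_index=draw(st.none() | st.integers(min_value=1, max_value=9)),
        sample_time=draw(st.none() | _finite),
        analyte_name=draw(st.none() | _name) if with_analyte else None,
        is_blank=draw(st.booleans()),
    )


# -- fixtures ----------------------------------------------------------------


@pytest.fixture
def table1_experiment():
    return fk.assemble_experiment(fk.table1_fixture(), "table1")


@pytest.fixture
def toy_model():
    return fk.toy_model_fixture()


@pytest.fixture
def clean_synthetic():
    """Noiseless, complete synthetic experiment (ground truth exact)."""
    points, truth = fk.generate_experiment(fk.SyntheticConfig(seed=11))
    return fk.assemble_experiment(points, "clean"), truth


@pytest.fixture
def trial_id():
    return fk.parse_identifier("strain:A|media:M9")


def make_course(ident, analyte_type, times, values, unit=""):
    return fk.AnalyteCourse(
        identifier=ident, analyte_type=analyte_type,
        times=np.asarray(times, float), values=np.asarray(values, float), unit=unit,
    )
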