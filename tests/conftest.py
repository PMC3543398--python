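import pytest

from cogrecov import AssessmentSeries


@pytest.fixture
def hand_cohort():
    """Two patients small enough to push through every formula by hand.

    Patient 1 recovers: anchors (5,20),(12,24); later assessments (19,26),(26,27).
    Patient 2 is flat at 15, so every tailored model predicts 15 everywhere.
    """
    return [
        AssessmentSeries("p1", ((5, 20), (12, 24), (19, 26), (26, 27))),
        AssessmentSeries("p2", ((6, 15), (13, 15), (20, 15), (27, 15))),
    ]
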