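import pytest

from protonrbe import LQParams


def bisect_iso_dose(alpha: float, beta: float, effect: float, tol: float = 1e-12) -> float:
    """Independent bisection oracle for the positive root of a*D + b*D^2 = E."""
    if effect == 0:
        return 0.0
    lo, hi = 0.0, 1.0
    while alpha * hi + beta * hi * hi < effect:
        hi *= 2.0
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if alpha * mid + beta * mid * mid < effect:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.fixture
def v79() -> LQParams:
    """The anchor cell line's low-LET parameters."""
    return LQParams(alpha=0.12, beta=0.035)
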