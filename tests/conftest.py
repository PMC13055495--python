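import warnings

import pytest

from multistress.io import example_coefficients


@pytest.fixture(scope="session")
def example_coefs():
    """Packaged example coefficient table keyed by (response, date_label)."""
    return {(c.response, c.date_label): c for c in example_coefficients()}


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def oracle_classify(beta_w, beta_p, beta_int, p_int, alpha=0.05):
    """Brute-force sign/magnitude oracle for the interaction taxonomy.

    Independent formulation: with delta_add = beta_w + beta_p,
      * synergism  iff sign(beta_int) == sign(delta_add)
      * antagonism iff sign(beta_int) == -sign(delta_add) and |beta_int| < |delta_add|
      * reversal   iff sign(beta_int) == -sign(delta_add) and |beta_int| > |delta_add|
      * |beta_int| == |delta_add| (combined effect exactly null), a zero
        interaction or zero delta_add -> indeterminate.
    The reversal code records the direction of the flip (from the additive
    expectation's sign); the S/A suffix is the combined effect's sign, which
    for non-reversals equals delta_add's sign.
    """
    if p_int >= alpha:
        return ("none", "NA")
    delta_add = beta_w + beta_p
    sgn = lambda x: int(x > 0) - int(x < 0)
    if sgn(beta_int) == 0 or sgn(delta_add) == 0:
        return ("indeterminate", "NA")
    if sgn(beta_int) == sgn(delta_add):
        return ("synergism", "S+" if delta_add > 0 else "S-")
    if abs(beta_int) == abs(delta_add):
        return ("indeterminate", "NA")
    if abs(beta_int) > abs(delta_add):
        return ("reversal", "R+/-" if delta_add > 0 else "R-/+")
    return ("antagonism", "A+" if delta_add > 0 else "A-")
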