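import numpy as np
import pytest

from mpfnet.nn import autograd as ag


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_gradient(fval, arrays, k, eps=1e-6):
    """Central finite differences of scalar fval(arrays) w.r.t. arrays[k]."""
    g = np.zeros_like(arrays[k])
    it = np.nditer(arrays[k], flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arrays[k][i]
        arrays[k][i] = orig + eps
        fp = fval(arrays)
        arrays[k][i] = orig - eps
        fm = fval(arrays)
        arrays[k][i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture
def gradcheck():
    """Compare analytic backprop to central differences for a tensor op."""

    def check(build, arrays, rtol=1e-6):
        def fval(arrs):
            return float(build(*[ag.Tensor(a) for a in arrs]).sum().data)

        ts = [ag.Tensor(a.copy(), requires_grad=True) for a in arrays]
        build(*ts).sum().backward()
        worst = 0.0
        for k, t in enumerate(ts):
            num = numeric_gradient(fval, [a.copy() for a in arrays], k)
            scale = max(1.0, float(np.abs(num).max()))
            worst = max(worst, float(np.abs(num - t.grad).max()) / scale)
        assert worst < rtol, f"gradient mismatch: {worst:.3g}"
        return worst

    return check
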