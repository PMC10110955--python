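import numpy as np
import pytest

from gpcal.synthetic import BleachModel, TransientKernel, kernel_from_kinetics, simulate_trace


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture
def standard_kernel():
    """A mid-range evoked transient (well resolved at 10 Hz)."""
    return kernel_from_kinetics(amplitude=0.05, fwhm=1.0, rise_10_90=0.23, onset_time=10.0)


@pytest.fixture
def noisy_event_trace(standard_kernel):
    """One bleached, noisy trace holding one event plus its ground truth."""
    trace, truth = simulate_trace(
        BleachModel(), [standard_kernel], noise_sd=0.3, duration=30.0, seed=7
    )
    return trace, truth


def dense_kernel_metrics(kernel: TransientKernel, dt: float = 1e-5) -> dict:
    """Independent brute-force oracle: scan the kernel on a dense grid.

    Locates the 10/50/90% threshold crossings by linear interpolation between
    grid samples, fully independent of the closed-form/brentq implementation.
    """
    t_end = kernel.onset_time + kernel.peak_delay + 20.0 * kernel.decay_tau
    t = np.arange(kernel.onset_time, t_end, dt)
    y = kernel.evaluate(t)
    ipk = int(np.argmax(y))
    peak = y[ipk]

    def crossing(level, lo, hi, rising):
        seg = y[lo:hi]
        idx = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level)) if rising else np.flatnonzero(
            (seg[:-1] >= level) & (seg[1:] < level)
        )
        i = idx[0] + lo
        frac = (level - y[i]) / (y[i + 1] - y[i])
        return t[i] + frac * dt

    t10u = crossing(0.1 * peak, 0, ipk + 1, True)
    t50u = crossing(0.5 * peak, 0, ipk + 1, True)
    t90u = crossing(0.9 * peak, 0, ipk + 1, True)
    t90d = crossing(0.9 * peak, ipk, y.size, False)
    t50d = crossing(0.5 * peak, ipk, y.size, False)
    t10d = crossing(0.1 * peak, ipk, y.size, False)
    return {
        "amplitude": float(peak),
        "peak_time": float(t[ipk]),
        "fwhm": float(t50d - t50u),
        "rise_10_90": float(t90u - t10u),
        "decay_90_10": float(t10d - t90d),
    }
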