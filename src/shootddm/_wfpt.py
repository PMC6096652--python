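"""Low-level numba kernels for the two-boundary Wiener first-passage problem.

Conventions used throughout:

* diffusion coefficient fixed at 1, time in seconds;
* ``a``  -- threshold separation (boundaries at 0 and ``a``);
* ``v``  -- drift rate, positive values point at the upper boundary;
* ``w``  -- relative start point, fraction of ``a`` measured from the
  lower boundary;
* densities are first-passage densities of the *decision* time (the
  non-decision time is added by the callers).

The density uses the classic small-time / large-time series pair with the
term-count rules of Navarro & Fuss (2009), switching to whichever series
needs fewer terms for the requested truncation error.
"""

import math

import numpy as np
from numba import njit

_TWO_PI = 2.0 * math.pi


@njit(cache=True)
def f0_lower(u, w, eps):
    """Standardized (a=1, v=0) lower-boundary density at scaled time u."""
    if u <= 1e-12:
        # every series term underflows long before this; avoids 0/0 in the
        # u**-1.5 prefactor for denormal u
        return 0.0
    # terms needed by the small-time representation
    if 2.0 * math.sqrt(_TWO_PI * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(_TWO_PI * u)))
        if ks < math.sqrt(u) + 1.0:
            ks = math.sqrt(u) + 1.0
    else:
        ks = 2.0
    # terms needed by the large-time representation
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        if kl < 1.0 / (math.pi * math.sqrt(u)):
            kl = 1.0 / (math.pi * math.sqrt(u))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))

    if ks < kl:
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        s = 0.0
        for k in range(lo, hi + 1):
            y = w + 2.0 * k
            s += y * math.exp(-y * y / (2.0 * u))
        return s / math.sqrt(_TWO_PI * u * u * u)
    K = int(math.ceil(kl))
    s = 0.0
    for k in range(1, K + 1):
        s += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
    return s * math.pi


@njit(cache=True)
def logpdf_lower(t, a, v, w, eps):
    """Log density of hitting the lower boundary at decision time t."""
    if t <= 0.0:
        return -np.inf
    u = t / (a * a)
    f = f0_lower(u, w, eps)
    if f <= 0.0:
        # truncation noise can dip below zero far in the tails
        return -np.inf
    return math.log(f) - 2.0 * math.log(a) - v * a * w - v * v * t / 2.0


@njit(cache=True)
def logpdf(t, upper, a, v, w, eps):
    """Log first-passage density; upper boundary via reflection v->-v, w->1-w."""
    if upper:
        return logpdf_lower(t, a, -v, 1.0 - w, eps)
    return logpdf_lower(t, a, v, w, eps)


@njit(cache=True)
def prob_upper(a, v, w):
    """Probability of absorption at the upper boundary (unbounded time)."""
    if v == 0.0:
        return w
    if v < 0.0:
        # mirror to keep every exponent non-positive
        a2 = -2.0 * (-v) * a
        num = math.expm1(a2 * (1.0 - w))
        den = math.expm1(a2)
        return 1.0 - num / den
    a2 = -2.0 * v * a
    return math.expm1(a2 * w) / math.expm1(a2)


@njit(cache=True)
def tail_mass_lower(t, a, v, w):
    """P(hit lower boundary at a decision time > t)."""
    if t <= 0.0:
        return prob_upper(a, -v, 1.0 - w)
    u = t / (a * a)
    if u < 1e-4:
        # essentially no mass is absorbed this early for w in (0, 1)
        return prob_upper(a, -v, 1.0 - w)
    pref = math.pi / (a * a) * math.exp(-v * a * w)
    s = 0.0
    for k in range(1, 1001):
        lam = v * v / 2.0 + k * k * math.pi * math.pi / (2.0 * a * a)
        term = k * math.exp(-lam * t) / lam * math.sin(k * math.pi * w)
        s += term
        if k > 2 and k * math.exp(-lam * t) / lam < 1e-12:
            break
    m = pref * s
    if m < 0.0:
        m = 0.0
    return m


@njit(cache=True)
def survivor(t, a, v, w):
    """P(no boundary has been crossed by decision time t)."""
    if t <= 0.0:
        return 1.0
    s = tail_mass_lower(t, a, v, w) + tail_mass_lower(t, a, -v, 1.0 - w)
    if s > 1.0:
        s = 1.0
    return s


@njit(cache=True)
def cdf_lower(t, a, v, w):
    """P(hit lower boundary at a decision time <= t)."""
    p = prob_upper(a, -v, 1.0 - w) - tail_mass_lower(t, a, v, w)
    if p < 0.0:
        p = 0.0
    return p


@njit(cache=True)
def _sim_one(a, v, w, ndt, dt, window_s):
    """One Euler-Maruyama walk with Brownian-bridge crossing correction.

    The bridge correction catches boundary crossings that occur between
    Euler grid points, removing the O(sqrt(dt)) bias of the raw scheme in
    choice and censoring probabilities.  Within-step crossing times are
    drawn uniformly over the step.  Returns (choice, rt_s).
    """
    sdt = math.sqrt(dt)
    x = w * a
    t = 0.0
    while True:
        xn = x + v * dt + sdt * np.random.normal()
        c = np.int8(-1)
        if xn >= a:
            c = 1
        elif xn <= 0.0:
            c = 0
        else:
            # probability that the bridge from x to xn touched a boundary;
            # skipped when it is below ~1e-9 to save the exp calls
            gu = (a - x) * (a - xn)
            gl = x * xn
            if gu < 10.0 * dt or gl < 10.0 * dt:
                p_up = math.exp(-2.0 * gu / dt)
                p_lo = math.exp(-2.0 * gl / dt)
                u = np.random.random()
                if u < p_up:
                    c = 1
                elif u < p_up + p_lo:
                    c = 0
        if c >= 0:
            t_cross = t + dt * np.random.random()
            if t_cross + ndt > window_s:
                return np.int8(-1), np.nan
            return c, t_cross + ndt
        t += dt
        x = xn
        if t + ndt > window_s:
            return np.int8(-1), np.nan
        if t > 120.0:
            # pathological region of parameter space; assign nearest side
            c = np.int8(1) if x >= a * 0.5 else np.int8(0)
            return c, t + ndt


@njit(cache=True)
def simulate_batch(n, a, v, w, ndt, dt, window_s, seed):
    """Simulate n trials with one parameter set.

    Returns (choice, rt_s): choice 1=upper, 0=lower, -1=censored;
    rt_s is NaN for censored trials. window_s may be inf.
    """
    np.random.seed(seed)
    choice = np.empty(n, np.int8)
    rt = np.empty(n, np.float64)
    for i in range(n):
        choice[i], rt[i] = _sim_one(a, v, w, ndt, dt, window_s)
    return choice, rt


@njit(cache=True)
def simulate_table(a, v, w, ndt, dt, window_s, seed):
    """Simulate one trial per row of the per-trial parameter arrays."""
    np.random.seed(seed)
    n = a.shape[0]
    choice = np.empty(n, np.int8)
    rt = np.empty(n, np.float64)
    for i in range(n):
        choice[i], rt[i] = _sim_one(a[i], v[i], w[i], ndt[i], dt, window_s)
    return choice, rt
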