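"""Robust adaptive unscented Kalman filter (RAUKF) for conductance
estimation from noisy voltage recordings.

The membrane state x = (V, gates) is augmented with the parameter vector
theta = [gM, gKdrf, gKa, gNa] (channel densities, S/cm^2); theta follows
a random walk while x follows the conductance-model dynamics, so one
filter pass over a current-clamp recording yields both hidden-state and
parameter estimates:

    X_k = F(X_{k-1}, u_{k-1}) + M_{k-1},   M ~ N(0, Q)
    y_k = V_k + n_k,                       n ~ N(0, R)

Sigma points drawn from the current posterior are propagated through the
full nonlinear model (each point carrying its own conductances) and a
standard unscented measurement update on the scalar voltage follows.

Robustness devices (each matters for spiking dynamics, where innovations
at slightly mis-timed spikes are tens of millivolts):

* every covariance is projected back onto the PSD cone after the
  unscented reconstruction (the scaled transform's large cancelling
  centre weight can otherwise leave it indefinite);
* the prediction falls back to the propagated central sigma point when
  the weighted-mean cancellation visibly fails;
* the parameter random walk uses magnitude-scaled noise that is annealed
  over the recording, and the parameters are held at their
  initialization during the zero-current lead-in while the hidden state
  locks on;
* the reported estimate is the trajectory average over the last two
  protocol repeats rather than the last sample, which removes the
  protocol-periodic component of the estimate wander.

A fault detector on the normalized innovation with fault-triggered
updates of Q and R (weights lambda0/delta0, gains a >> b) is available
for recordings whose noise statistics are not known; with the
self-generated protocol the noise levels are exact, so the default run
leaves Q and R fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from . import _kernel
from .model import MembraneModel


@dataclass(frozen=True)
class RAUKFConfig:
    alpha: float = 1e-3        # sigma-point spread
    beta: float = 2.0          # prior-distribution weighting (Gaussian: 2)
    kappa: float = 0.0
    lambda0: float = 0.2       # minimum Q adaptation weight
    delta0: float = 0.2        # minimum R adaptation weight
    a: float = 10.0            # fault-proportional gain on Q updates
    b: float = 1.0             # fault-proportional gain on R updates
    fault_p: float = 0.05      # chi-square tail probability of the detector

    def __post_init__(self):
        if not (0 < self.lambda0 <= 1 and 0 < self.delta0 <= 1):
            raise ValueError("lambda0 and delta0 must be in (0, 1]")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")

    @property
    def fault_threshold(self) -> float:
        return float(chi2.ppf(1.0 - self.fault_p, df=1))


# ---------------------------------------------------------------------------
# unscented-transform primitives
# ---------------------------------------------------------------------------

def sigma_points(mean: np.ndarray, cov: np.ndarray,
                 cfg: RAUKFConfig = RAUKFConfig()):
    """Scaled symmetric sigma points and their mean/covariance weights.

    Returns (points, wm, wc) with points of shape (2n+1, n).  The
    covariance is jitter-regularized before factorization; a failure
    after regularization raises.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    n = mean.size
    lam = cfg.alpha ** 2 * (n + cfg.kappa) - n
    scale = n + lam
    try:
        L = np.linalg.cholesky(scale * cov)
    except np.linalg.LinAlgError:
        jitter = 1e-12 * max(1.0, np.trace(cov) / n)
        try:
            L = np.linalg.cholesky(scale * cov + jitter * np.eye(n))
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "sigma-point factorization failed after regularization") from e
    pts = np.empty((2 * n + 1, n))
    pts[0] = mean
    pts[1:n + 1] = mean + L.T
    pts[n + 1:] = mean - L.T
    wm = np.full(2 * n + 1, 1.0 / (2.0 * scale))
    wc = wm.copy()
    wm[0] = lam / scale
    wc[0] = lam / scale + (1.0 - cfg.alpha ** 2 + cfg.beta)
    return pts, wm, wc


def psd_repair(P: np.ndarray, floor_scale: float = 1e-12) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue floor)."""
    P = 0.5 * (P + P.T)
    w, V = np.linalg.eigh(P)
    floor = floor_scale * max(1.0, float(w.max()))
    if w[0] >= floor:
        return P
    w = np.clip(w, floor, None)
    return (V * w) @ V.T


def unscented_transform(pts: np.ndarray, wm: np.ndarray, wc: np.ndarray):
    mean = wm @ pts
    dev = pts - mean
    cov = (wc[:, None] * dev).T @ dev
    return mean, cov


def unscented_transform_central(pts: np.ndarray, wc: np.ndarray):
    """Central-point variant of the transform (divergence fallback).

    The propagated central sigma point serves as the mean and deviations
    are taken about it, so the huge cancelling centre weight of the
    scaled transform (order 1/alpha^2) never multiplies a nonlinearly
    amplified spread.  Exact for linear dynamics.
    """
    mean = pts[0]
    dev = pts[1:] - mean
    cov = (wc[1:, None] * dev).T @ dev
    return mean, cov


def predict(x: np.ndarray, P: np.ndarray, Q: np.ndarray, propagate,
            cfg: RAUKFConfig = RAUKFConfig()):
    """Unscented prediction: push sigma points through ``propagate``.

    ``propagate`` maps a (2n+1, n) array of states to the same shape (it
    may mutate in place and return its argument).  Returns the prior
    (x_prior, P_prior) with Q added.
    """
    pts, wm, wc = sigma_points(x, P, cfg)
    pts = propagate(pts)
    if not np.all(np.isfinite(pts)):
        bad = int(np.flatnonzero(~np.isfinite(pts).all(axis=1))[0])
        raise FloatingPointError(
            f"integration failure on sigma point {bad}")
    x_std, P_std = unscented_transform(pts, wm, wc)
    # spike upstrokes can amplify the spread so nonlinearly that the
    # scaled-UT mean cancellation fails by orders of magnitude; detect a
    # non-physical mean on the observed component and fall back
    if not np.all(np.isfinite(x_std)) or abs(x_std[0] - pts[0, 0]) > 25.0:
        x_ctr, P_ctr = unscented_transform_central(pts, wc)
        return x_ctr, psd_repair(P_ctr + Q)
    return x_std, psd_repair(P_std + Q)


def update(x_prior: np.ndarray, P_prior: np.ndarray, y: float, R: float,
           obs_index: int = 0, huber_k: float | None = None):
    """Scalar measurement update observing one state component.

    With ``huber_k`` the innovation applied to the state is saturated at
    that many standard deviations of the predicted observation spread
    (the raw innovation is still returned for the fault detector).
    Returns (x_post, P_post, innovation, S, K).
    """
    S = P_prior[obs_index, obs_index] + R
    K = P_prior[:, obs_index] / S
    nu = float(y - x_prior[obs_index])
    if not np.isfinite(nu):
        raise FloatingPointError("non-finite innovation")
    nu_used = nu
    if huber_k is not None:
        bound = huber_k * np.sqrt(S)
        nu_used = float(np.clip(nu, -bound, bound))
    x_post = x_prior + K * nu_used
    P_post = psd_repair(P_prior - np.outer(K, K) * S)
    return x_post, P_post, nu, float(S), K


def adapt_noise(nu: float, S: float, K: np.ndarray, Q: np.ndarray, R: float,
                cfg: RAUKFConfig = RAUKFConfig(),
                r_floor: float = 1e-6, n_adapt: int | None = None,
                nu2_avg: float | None = None):
    """Fault-triggered covariance adaptation.

    The innovation is tested against what the observation noise explains
    (phi = nu^2/R versus a chi-square(1) threshold T).  Without a fault,
    Q and R are returned unchanged.  On a fault, both move toward
    instantaneous estimates by convex combination; the weights grow with
    the fault magnitude (lambda = clip(lambda0 * a * phi/T, lambda0, 1)
    and likewise delta with gain b), so Q reacts much more aggressively
    than R when a >> b.

    ``nu2_avg`` is an optional short-window average of the squared
    innovations: a single nu^2 is one chi-square draw, so using the
    windowed value for the R estimate removes most of the estimator's
    variance.  ``n_adapt`` limits the Q update to the leading block (the
    membrane states): the parameter random walk is a regularizer whose
    scale is set by the magnitude rule, and letting voltage-scale
    innovation variance leak into it destabilizes the static-parameter
    estimates.  Returns (Q, R, fault, phi).
    """
    phi = nu * nu / max(R, r_floor)
    T = cfg.fault_threshold
    if phi <= T:
        return Q, R, False, phi
    lam = min(1.0, max(cfg.lambda0, cfg.lambda0 * cfg.a * phi / T))
    dlt = min(1.0, max(cfg.delta0, cfg.delta0 * cfg.b * phi / T))
    m = Q.shape[0] if n_adapt is None else n_adapt
    Q_new = Q.copy()
    Q_est = np.outer(K[:m], K[:m]) * (nu * nu)
    Q_new[:m, :m] = (1.0 - lam) * Q[:m, :m] + lam * Q_est
    nu2 = nu * nu if nu2_avg is None else nu2_avg
    R_est = max(r_floor, nu2 - (S - R))
    R_new = (1.0 - dlt) * R + dlt * R_est
    return Q_new, R_new, True, phi


def percent_difference(estimate, reference):
    """|est - ref| / ref * 100 per component; nan where ref = 0."""
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    out = np.full(np.broadcast(est, ref).shape, np.nan)
    nz = ref != 0
    out[nz] = np.abs(est - ref)[nz] / np.abs(ref)[nz] * 100.0
    return out


# ---------------------------------------------------------------------------
# full filter over a membrane-model recording
# ---------------------------------------------------------------------------

ESTIMATED_CHANNELS = ("M", "Kdrf", "Ka", "Na")

#: Relative random-walk scale per parameter: the per-step noise sd is
#: this fraction of the parameter's order of magnitude.  The small, slow
#: M conductance gets a slightly stiffer walk (its late wander, not its
#: convergence speed, limits accuracy).
THETA_WALK_SCALE = np.array([0.007, 0.01, 0.01, 0.01])

#: Default recording step (ms) and observation-noise sd (mV) of the
#: self-generated estimation protocol: a 10 kHz, low-noise whole-cell
#: recording of the model.
OBS_DT = 0.1
OBS_NOISE_SD = 0.03


def theta_from_model(model: MembraneModel) -> np.ndarray:
    """Reference conductance densities [gM, gKdrf, gKa, gNa] in S/cm^2."""
    if model.area_cm2 is None:
        raise ValueError("model needs area_cm2 to express densities")
    f = 1e-6 / model.area_cm2
    return np.array([model.channel(n).gbar * f for n in ESTIMATED_CHANNELS])


def poor_theta(theta: np.ndarray) -> np.ndarray:
    """Order-of-magnitude initialization: 10^floor(log10 theta)."""
    return 10.0 ** np.floor(np.log10(theta))


def magnitude_init(theta: np.ndarray):
    """(P_theta, Q_theta) diagonals from the order of magnitude of theta.

    The prior variance doubles the order of magnitude
    (P_ii = 10^(2 m_i), m_i = floor(log10 theta_i)), i.e. a prior sd of
    one magnitude unit; the random-walk noise sd is a small fraction of
    the magnitude (see THETA_WALK_SCALE).
    """
    m = np.floor(np.log10(theta))
    mag = 10.0 ** m
    return mag ** 2, (THETA_WALK_SCALE * mag) ** 2


@dataclass
class EstimateTrajectory:
    t: np.ndarray                  # ms, subsampled recording times
    theta: np.ndarray              # (len(t), 4) estimates
    stderr: np.ndarray             # (len(t), 4) sqrt of P theta-diagonal
    final_theta: np.ndarray        # tail-averaged estimate (see run_raukf)
    final_stderr: np.ndarray
    fault_times: np.ndarray
    innovations: np.ndarray        # subsampled
    reference: np.ndarray | None = None
    theta_names: tuple = ESTIMATED_CHANNELS

    @property
    def percent_diff(self) -> np.ndarray | None:
        if self.reference is None:
            return None
        return percent_difference(self.final_theta, self.reference)


def run_raukf(observation: np.ndarray, u: np.ndarray, theta0: np.ndarray,
              model: MembraneModel, cfg: RAUKFConfig = RAUKFConfig(),
              dt: float = OBS_DT, R0: float = OBS_NOISE_SD ** 2,
              Px0: float = 1e-4, Qx0: float = 1e-8,
              v0: float | None = None, reference=None,
              record_every: int = 40,
              divergence_limit: float = 1e4,
              theta_P0=None, theta_Q=None,
              theta_Q_halflife: float | None = 150.0,
              theta_Q_burn: float = 0.0,
              theta_freeze_ms: float = 500.0,
              huber_k: float | None = None,
              adapt: bool = False,
              final_average_ms: float = 2744.0) -> EstimateTrajectory:
    """Filter a voltage recording, estimating the four channel densities.

    ``observation`` (mV) and ``u`` (pA, known injected current) are
    aligned per-sample series at spacing ``dt``.  ``theta0`` is the
    parameter initialization in S/cm^2 (optimized: the true values;
    poor: their order of magnitude).  ``R0`` should be the
    observation-noise variance when known.  One predict/update cycle
    runs per sample; the parameters are held for the first
    ``theta_freeze_ms`` (the protocol lead-in) and their random-walk
    noise is annealed with the given half-life.  The reported final
    estimate averages the trajectory over the last ``final_average_ms``
    (two protocol repeats by default).
    """
    observation = np.asarray(observation, dtype=float)
    u = np.asarray(u, dtype=float)
    if observation.shape != u.shape:
        raise ValueError("observation and input must align")
    theta0 = np.asarray(theta0, dtype=float)
    if theta0.size != len(ESTIMATED_CHANNELS):
        raise ValueError("theta0 must have 4 components")
    if model.area_cm2 is None:
        raise ValueError("model needs area_cm2 for density <-> gbar")
    dens2gbar = model.area_cm2 * 1e6

    pk = model.pack()
    names = [c.name for c in model.channels]
    est_idx = np.array([names.index(n) for n in ESTIMATED_CHANNELS])
    G = pk["gate_chan"].size
    n_x = 1 + G
    n = n_x + 4
    n_sig = 2 * n + 1

    # initial state: observation's first value, gates at steady state there
    x0 = observation[0] if v0 is None else v0
    X = np.empty(n)
    X[0] = x0
    X[1:n_x] = model.steady_gates(x0)
    X[n_x:] = theta0
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    Pth, Qth = magnitude_init(theta0)
    if theta_P0 is not None:
        Pth = np.asarray(theta_P0, dtype=float)
    if theta_Q is not None:
        Qth = np.asarray(theta_Q, dtype=float)
    np.fill_diagonal(P[:n_x, :n_x], Px0)
    np.fill_diagonal(Q[:n_x, :n_x], Qx0)
    P[n_x:, n_x:] = np.diag(Pth)
    Q[n_x:, n_x:] = np.diag(Qth)
    R = float(R0)

    gbar_batch = np.tile(pk["gbar"], (n_sig, 1))

    def propagate(pts, iin):
        # clip gates and parameters into their physical ranges
        np.clip(pts[:, 1:n_x], 0.0, 1.0, out=pts[:, 1:n_x])
        np.clip(pts[:, n_x:], 0.0, None, out=pts[:, n_x:])
        gbar_batch[:, est_idx] = pts[:, n_x:] * dens2gbar
        V = np.ascontiguousarray(pts[:, 0])
        gates = np.ascontiguousarray(pts[:, 1:n_x])
        _kernel.step_batch(V, gates, gbar_batch, pk["erev"],
                           pk["gate_chan"], pk["gate_pow"], pk["inf_vh"],
                           pk["inf_k"], pk["tau_form"], pk["tau_p"],
                           model.capacitance, dt, iin)
        pts[:, 0] = V
        pts[:, 1:n_x] = gates
        return pts

    nt = observation.size
    rec_t, rec_theta, rec_err, rec_nu = [], [], [], []
    fault_times = []
    Qth_base = Qth.copy()
    nu2_avg = None
    for k in range(1, nt):
        if theta_Q_halflife is not None:
            t_past = max(0.0, k * dt - theta_Q_burn)
            decay = 1.0 / (1.0 + t_past / theta_Q_halflife)
            Q[n_x:, n_x:] = np.diag(Qth_base * decay)
        iin = u[k - 1]
        Xp, Pp = predict(X, P, Q, lambda pts: propagate(pts, iin), cfg)
        X, P, nu, S, K = update(Xp, Pp, observation[k], R, huber_k=huber_k)
        if k * dt < theta_freeze_ms:
            # lead-in warm-up: hold the parameters and their prior while
            # the hidden membrane state locks onto the recording
            X[n_x:] = theta0
            P[n_x:, :] = 0.0
            P[:, n_x:] = 0.0
            P[n_x:, n_x:] = np.diag(Pth)
        np.clip(X[n_x:], 0.0, None, out=X[n_x:])
        if abs(nu) > divergence_limit:
            raise FloatingPointError(
                f"filter divergence at t = {k * dt:.2f} ms "
                f"(innovation {nu:.3g} mV)")
        if adapt:
            nu2_avg = (nu * nu if nu2_avg is None
                       else 0.95 * nu2_avg + 0.05 * nu * nu)
            Q, R, fault, _ = adapt_noise(nu, S, K, Q, R, cfg, n_adapt=n_x,
                                         nu2_avg=nu2_avg)
            if fault:
                fault_times.append(k * dt)
            Qth_base = np.diag(Q[n_x:, n_x:]).copy()
        if k % record_every == 0 or k == nt - 1:
            rec_t.append(k * dt)
            rec_theta.append(X[n_x:].copy())
            rec_err.append(np.sqrt(np.abs(np.diag(P)[n_x:])))
            rec_nu.append(nu)
    t = np.array(rec_t)
    theta_traj = np.vstack(rec_theta)
    err_traj = np.vstack(rec_err)
    tail = t > t[-1] - final_average_ms
    return EstimateTrajectory(
        t=t, theta=theta_traj, stderr=err_traj,
        final_theta=theta_traj[tail].mean(axis=0),
        final_stderr=err_traj[tail].mean(axis=0),
        fault_times=np.array(fault_times), innovations=np.array(rec_nu),
        reference=(None if reference is None
                   else np.asarray(reference, dtype=float)))


def make_observation(model: MembraneModel, dt: float = OBS_DT,
                     seed: int | None = 0,
                     noise_sd_mV: float = OBS_NOISE_SD,
                     train_cfg=None):
    """Generate the noisy step-train voltage observation from the model.

    Returns (observation mV, input pA, clean V).  The injected current
    is the noisy step train (its 4-pA noise mean carries the bias
    current); observation noise of sd ``noise_sd_mV`` is added to the
    simulated voltage.
    """
    from .model import run_batch
    from .stimuli import RAUKFTrain, raukf_train
    rng = np.random.default_rng(seed)
    cfg = train_cfg or RAUKFTrain()
    stim = raukf_train(cfg, dt, seed=rng)
    V, _, _, _ = run_batch(model, stim, cfg.total_duration, dt)
    clean = V[0]
    obs = clean + noise_sd_mV * rng.standard_normal(clean.size)
    return obs, stim, clean


def recover_conductances(model: MembraneModel, init: str = "poor",
                         seed: int | None = 0,
                         cfg: RAUKFConfig = RAUKFConfig(),
                         noise_sd_mV: float = OBS_NOISE_SD,
                         dt: float = OBS_DT) -> EstimateTrajectory:
    """Self-recovery convenience: observe the model, then estimate it.

    ``init`` is "optimal" (start at the true conductances) or "poor"
    (start at their order of magnitude).
    """
    if init not in ("optimal", "poor"):
        raise ValueError("init must be 'optimal' or 'poor'")
    truth = theta_from_model(model)
    obs, u, _ = make_observation(model, dt=dt, seed=seed,
                                 noise_sd_mV=noise_sd_mV)
    theta0 = truth.copy() if init == "optimal" else poor_theta(truth)
    return run_raukf(obs, u, theta0, model, cfg, dt=dt,
                     R0=noise_sd_mV ** 2, reference=truth)
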