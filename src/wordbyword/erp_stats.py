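"""Window-mean amplitudes and repeated-measures ANOVA for ERP effects.

Component effects are quantified as arithmetic mean amplitudes over
fixed post-onset windows (P200 166-336 ms, N400 350-500 ms, P600
500-650 ms, N100 60-160 ms) at midline electrodes {Fz, Cz, CPz, Pz} or
four lateral quadrant averages.  Congruency x site effects are tested
with two-way repeated-measures ANOVAs implemented from the
sum-of-squares definitions; sphericity is checked with Mauchly's test
and, when violated, p-values are Greenhouse-Geisser corrected (reported
with the original degrees of freedom).  Effect sizes are partial eta
squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .montage import MIDLINE, QUADRANTS


@dataclass(frozen=True)
class WindowSpec:
    name: str
    window_ms: tuple[float, float]


DEFAULT_WINDOWS = {
    "P200": WindowSpec("P200", (166.0, 336.0)),
    "N400": WindowSpec("N400", (350.0, 500.0)),
    "P600": WindowSpec("P600", (500.0, 650.0)),
    "N100": WindowSpec("N100", (60.0, 160.0)),
}

MIDLINE_SITES = {name: (name,) for name in MIDLINE}
QUADRANT_SITES = dict(QUADRANTS)


# ----------------------------------------------------------------------
# window means


def window_mean(
    data: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    channels: tuple[str, ...],
    electrodes,
) -> float:
    """Mean amplitude over a time window and an electrode set.

    ``data`` is channels x samples (an ERP) or trials x channels x
    samples (epochs, averaged first).  The window is inclusive on both
    edges; electrode averaging happens before time averaging (the two
    commute for plain means).
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 3:
        data = data.mean(axis=0)
    if data.shape[0] != len(channels) or data.shape[1] != times_ms.size:
        raise ValueError("data shape does not match channels/times")
    tmask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not tmask.any():
        raise ValueError(f"window {window_ms} outside epoch")
    rows = [channels.index(e) for e in electrodes]
    return float(data[np.ix_(rows, np.flatnonzero(tmask))].mean())


def window_extremum(
    data: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    channels: tuple[str, ...],
    electrode: str,
    polarity: int,
    smooth_ms: float = 40.0,
) -> float:
    """Signed peak of a (difference) wave inside an analysis window.

    ``polarity`` +1 takes the maximum, -1 the minimum.  The trace is
    first smoothed with a short moving average (components here are an
    order of magnitude broader), which suppresses the upward bias that
    taking a window extremum of a noisy curve would otherwise add.
    """
    x = np.asarray(data, dtype=np.float64)[channels.index(electrode)]
    if smooth_ms > 0:
        dt = float(times_ms[1] - times_ms[0])
        n = max(1, int(round(smooth_ms / dt)))
        x = np.convolve(x, np.ones(n) / n, mode="same")
    m = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    seg = x[m]
    return float(seg.max() if polarity > 0 else seg.min())


def window_means_table(
    erps: dict,
    times_ms: np.ndarray,
    channels: tuple[str, ...],
    window_ms: tuple[float, float],
    sites: dict | None = None,
) -> pd.DataFrame:
    """Subject x condition x site table of window-mean amplitudes.

    ``erps`` maps ``(subject, condition)`` to a channels x samples ERP;
    ``sites`` maps site name to an electrode tuple (defaults to the
    midline electrodes).
    """
    sites = sites or MIDLINE_SITES
    rows = [
        dict(
            subject=subj, condition=cond, site=site,
            amplitude_uv=window_mean(erp, times_ms, window_ms, channels, electrodes),
        )
        for (subj, cond), erp in erps.items()
        for site, electrodes in sites.items()
    ]
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# sphericity


def gg_epsilon(table: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of an n-subjects x k-levels table."""
    Y = np.asarray(table, dtype=np.float64)
    n, k = Y.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 levels and >= 2 subjects")
    S = np.cov(Y, rowvar=False, ddof=1)
    return _epsilon_from_cov(S, _orthonormal_contrasts(k))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1.0)
        C[i] /= np.linalg.norm(C[i])
    return C


def _epsilon_from_cov(S: np.ndarray, C: np.ndarray) -> float:
    if C.shape[0] == 0:
        return 1.0
    T = C @ np.atleast_2d(S) @ C.T
    d = T.shape[0]
    if d == 0:
        return 1.0
    tr = np.trace(T)
    eps = tr**2 / (d * np.sum(T * T))
    return float(np.clip(eps, 1.0 / d, 1.0))


def mauchly_test(samples: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity statistic W and its chi-square p-value.

    ``samples`` is n x k (subject scores on k conditions), ``C`` the
    orthonormal contrast matrix of the tested effect.
    """
    n, k = samples.shape
    if k < 2 or C.shape[0] < 2:
        return 1.0, 1.0
    T = C @ np.atleast_2d(np.cov(samples, rowvar=False, ddof=1)) @ C.T
    d = T.shape[0]
    if d < 2:
        return 1.0, 1.0
    eig = np.linalg.eigvalsh(T)
    eig = np.maximum(eig, 1e-30)
    W = float(np.prod(eig) / (np.mean(eig) ** d))
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(max(W, 1e-300))
    df = d * (d + 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, df))
    return W, p


# ----------------------------------------------------------------------
# repeated-measures ANOVA


def _effect_stats(ss_eff, df_eff, ss_err, df_err, eps, mauchly_p, alpha=0.05):
    ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
    F = ms_eff / ms_err if ms_err > 0 else np.inf
    p_unc = float(stats.f.sf(F, df_eff, df_err))
    p_gg = float(stats.f.sf(F, df_eff * eps, df_err * eps))
    corrected = (mauchly_p < alpha) and df_eff > 1
    return dict(
        F=float(F), df1=df_eff, df2=df_err, ss_effect=float(ss_eff),
        ss_error=float(ss_err), gg_epsilon=float(eps),
        mauchly_p=float(mauchly_p), p_uncorrected=p_unc, p_gg=p_gg,
        p=(p_gg if corrected else p_unc), sphericity_corrected=bool(corrected),
        partial_eta_sq=float(ss_eff / (ss_eff + ss_err)) if ss_eff + ss_err > 0 else 0.0,
    )


def rm_anova_cube(Y: np.ndarray, factor_names=("A", "B"), alpha: float = 0.05) -> pd.DataFrame:
    """Two-way fully within-subject ANOVA on an (n, a, b) data cube.

    Returns one row per effect (two mains + interaction) with F, the
    original degrees of freedom, Greenhouse-Geisser epsilon, Mauchly's
    p, the (corrected where indicated) p-value and partial eta squared.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim != 3:
        raise ValueError("cube must be subjects x levelsA x levelsB")
    n, a, b = Y.shape
    if n < 2:
        raise ValueError("need >= 2 subjects")
    gm = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    ss_total = np.sum((Y - gm) ** 2)
    ss_subj = a * b * np.sum((m_s - gm) ** 2)
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    Ca, Cb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    flat = Y.reshape(n, a * b)

    effects = []
    if a > 1:
        # main effect A: subject scores collapsed over B
        Wp_a = mauchly_test(m_sa, Ca)[1]
        eps_a = _epsilon_from_cov(np.cov(m_sa, rowvar=False, ddof=1), Ca)
        effects.append(
            dict(effect=factor_names[0], **_effect_stats(
                ss_a, a - 1, ss_as, (a - 1) * (n - 1), eps_a, Wp_a, alpha))
        )
    if b > 1:
        Wp_b = mauchly_test(m_sb, Cb)[1]
        eps_b = _epsilon_from_cov(np.cov(m_sb, rowvar=False, ddof=1), Cb)
        effects.append(
            dict(effect=factor_names[1], **_effect_stats(
                ss_b, b - 1, ss_bs, (b - 1) * (n - 1), eps_b, Wp_b, alpha))
        )
    if a > 1 and b > 1:
        Cab = np.kron(Ca, Cb)
        S_flat = np.cov(flat, rowvar=False, ddof=1)
        Wp_ab = mauchly_test(flat, Cab)[1]
        eps_ab = _epsilon_from_cov(S_flat, Cab)
        effects.append(
            dict(effect=f"{factor_names[0]} x {factor_names[1]}", **_effect_stats(
                ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1),
                eps_ab, Wp_ab, alpha))
        )
    return pd.DataFrame(effects)


def rm_anova(
    table: pd.DataFrame,
    dv: str = "amplitude_uv",
    within: tuple[str, str] = ("condition", "site"),
    subject: str = "subject",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on a long-format table.

    The design must be balanced and complete (the pipeline balances
    trial counts upstream); factor level order follows first appearance.
    """
    fa, fb = within
    a_levels = list(pd.unique(table[fa]))
    b_levels = list(pd.unique(table[fb]))
    subjects = list(pd.unique(table[subject]))
    piv = table.pivot_table(
        index=subject, columns=[fa, fb], values=dv, aggfunc="mean", observed=False
    )
    expected = [(x, y) for x in a_levels for y in b_levels]
    if piv.isna().any().any() or len(piv.columns) != len(expected) or len(
        table
    ) != len(subjects) * len(expected):
        raise ValueError("unbalanced or incomplete within-subject design")
    cube = np.stack(
        [
            np.array([[piv.loc[s, (x, y)] for y in b_levels] for x in a_levels])
            for s in subjects
        ]
    )
    return rm_anova_cube(cube, factor_names=(fa, fb), alpha=alpha)


def n100_word_position_analysis(
    table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Word-position (1-4) x midline-electrode ANOVA on 60-160 ms means.

    ``table`` is long-format with columns subject, word_position, site,
    amplitude_uv (the N100-window means of heard words 1-4); delegates
    to the generic repeated-measures ANOVA.
    """
    positions = sorted(pd.unique(table["word_position"]))
    if len(positions) < 2:
        raise ValueError("need word positions 1..4")
    return rm_anova(
        table, dv="amplitude_uv", within=("word_position", "site"), alpha=alpha
    )
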