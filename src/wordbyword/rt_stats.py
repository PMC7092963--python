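"""Reaction-time extraction, exclusion rules, and gamma GLMM analysis.

The reaction time to speak is the interval from a word's visual
presentation to the speaker's refined speech onset.  RTs outside
(300 ms, 1000 ms) are excluded (strict bounds; boundary values kept),
as are words whose preceding spoken word had not terminated before the
visual presentation (detected from refined offsets).  Congruency and
word-position effects are modelled per spoken-word sequence (CW,CW+2,
CW+4 spoken by the critical-word producer; CW+1,CW+3,CW+5 by the
perceiver) with a gamma GLMM, inverse link, fixed congruency +
word-position effects and random intercepts for participant and for
word length (letter count), fitted by lme4's ``glmer`` through an R
subprocess; model comparison uses likelihood-ratio tests.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

RT_MIN_S = 0.3
RT_MAX_S = 1.0

SEQ_CW_EVEN = "cw_even"   # CW, CW+2, CW+4 (positions 8, 10, 12)
SEQ_CW_ODD = "cw_odd"     # CW+1, CW+3, CW+5 (positions 9, 11, 13)


def sequence_tag(word_position: int) -> str:
    if word_position in (8, 10, 12):
        return SEQ_CW_EVEN
    if word_position in (9, 11, 13):
        return SEQ_CW_ODD
    return "other"


# ----------------------------------------------------------------------
# extraction


def extract_rts(
    refined_events: pd.DataFrame, session_events: pd.DataFrame, plan
) -> pd.DataFrame:
    """Build the RT table from refined speech events and visual events.

    ``refined_events`` carries (participant, trial, word_position, kind,
    time, source); ``session_events`` the marker stream with
    ``event_type == 'visual'`` rows.  RT = speech onset - visual onset
    for the participant who spoke the word; each row also carries the
    previous spoken word's refined offset for the overlap rule.
    """
    vis = session_events[session_events.event_type == "visual"][
        ["trial", "word_position", "speaker", "congruency", "onset_s"]
    ].rename(columns={"onset_s": "t_visual_s", "speaker": "participant"})
    on = refined_events[refined_events.kind == "onset"][
        ["participant", "trial", "word_position", "time", "source"]
    ].rename(columns={"time": "onset_s"})
    off = refined_events[refined_events.kind == "offset"][
        ["trial", "word_position", "time"]
    ].rename(columns={"time": "offset_s"})

    df = vis.merge(on, on=["trial", "word_position", "participant"], how="inner")
    prev = off.assign(word_position=off.word_position + 1).rename(
        columns={"offset_s": "prev_offset_s"}
    )
    df = df.merge(prev, on=["trial", "word_position"], how="left")

    words = {
        t.trial_index: t.sentence.words for t in plan.trials
    }
    df["word"] = [
        words[tr][pos - 1] for tr, pos in zip(df.trial, df.word_position)
    ]
    df["word_length"] = df["word"].str.len()
    df["rt_s"] = df.onset_s - df.t_visual_s
    df["sequence"] = df.word_position.map(sequence_tag)
    return df.sort_values(["trial", "word_position"]).reset_index(drop=True)


def filter_rts(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion rules; returns the flagged table and a report.

    Strictly-outside bounds are excluded (rt exactly 0.3 or 1.0 s is
    kept); the overlap rule drops words whose preceding spoken word's
    refined offset exceeds the visual onset.
    """
    t = table.copy()
    too_fast = t.rt_s < RT_MIN_S
    too_slow = t.rt_s > RT_MAX_S
    overlap = t.prev_offset_s.notna() & (t.prev_offset_s > t.t_visual_s)
    t["excluded"] = too_fast | too_slow | overlap
    reasons = np.where(
        too_fast, "rt_below_bound",
        np.where(too_slow, "rt_above_bound", np.where(overlap, "overlap", "")),
    )
    t["exclusion_reason"] = reasons
    n = len(t)
    report = dict(
        n_words=n,
        n_excluded=int(t.excluded.sum()),
        n_rt_bounds=int((too_fast | too_slow).sum()),
        n_overlap=int(overlap.sum()),
        frac_excluded=float(t.excluded.mean()) if n else 0.0,
        frac_rt_bounds=float((too_fast | too_slow).mean()) if n else 0.0,
        frac_overlap=float(overlap.mean()) if n else 0.0,
    )
    return t, report


# ----------------------------------------------------------------------
# gamma GLMM via lme4


@dataclass
class GlmmFit:
    model: str                       # full | no_congruency | no_position
    sequence: str
    coef: dict                       # link-scale fixed effects
    se: dict
    random_sd: dict                  # participant / word_length intercept SDs
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    messages: list = field(default_factory=list)
    predicted_rt: dict = field(default_factory=dict)  # back-transformed means

    def predict_means(self) -> dict:
        """Back-transformed (1/eta) condition means at the average word
        position; requires the congruency covariate in the model."""
        b0 = self.coef.get("(Intercept)", np.nan)
        bc = self.coef.get("x_cong", 0.0)
        return {
            "grand": 1.0 / b0,
            "congruent": 1.0 / (b0 - 0.5 * bc),
            "incongruent": 1.0 / (b0 + 0.5 * bc),
        }


_R_TEMPLATE = r"""
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
out <- list()
fit_one <- function(df, form, name) {
  res <- tryCatch({
    m <- glmer(form, data = df, family = Gamma(link = "inverse"))
    msgs <- unlist(m@optinfo$conv$lme4$messages)
    list(model = name,
         coef = as.list(fixef(m)),
         se = as.list(sqrt(diag(as.matrix(vcov(m))))),
         random_sd = as.list(sapply(VarCorr(m), function(v) attr(v, "stddev")[[1]])),
         loglik = as.numeric(logLik(m)),
         n_params = attr(logLik(m), "df"),
         n_obs = nrow(df),
         converged = is.null(msgs),
         messages = if (is.null(msgs)) list() else as.list(msgs))
  }, error = function(e) list(model = name, error = conditionMessage(e)))
  res
}
models <- strsplit(args[3], ",")[[1]]
formulas <- list(
  full = rt_s ~ x_cong + pos_lin + pos_quad + (1 | participant) + (1 | word_length),
  no_congruency = rt_s ~ pos_lin + pos_quad + (1 | participant) + (1 | word_length),
  no_position = rt_s ~ x_cong + (1 | participant) + (1 | word_length)
)
for (ds in unique(d$dataset)) {
  df <- d[d$dataset == ds, ]
  df$participant <- factor(df$participant)
  df$word_length <- factor(df$word_length)
  fits <- lapply(models, function(nm) fit_one(df, formulas[[nm]], nm))
  out[[as.character(ds)]] <- fits
}
writeLines(toJSON(out, auto_unbox = TRUE, digits = 12), args[2])
"""


def _position_contrasts(positions: pd.Series) -> pd.DataFrame:
    """Orthogonal polynomial contrasts for the ordered 3-level position."""
    levels = np.sort(positions.unique())
    k = len(levels)
    x = np.arange(k, dtype=float)
    x -= x.mean()
    lin = x / np.sqrt(np.sum(x**2))
    quad = x**2 - np.mean(x**2)
    if np.allclose(quad, 0):
        quad = np.zeros(k)
    else:
        quad -= (quad @ lin) * lin
        quad /= np.sqrt(np.sum(quad**2))
    lut_lin = dict(zip(levels, lin))
    lut_quad = dict(zip(levels, quad))
    return pd.DataFrame({
        "pos_lin": positions.map(lut_lin),
        "pos_quad": positions.map(lut_quad),
    })


def _design_frame(table: pd.DataFrame, sequence: str) -> pd.DataFrame:
    t = table[(table.sequence == sequence)]
    if "excluded" in t.columns:
        t = t[~t.excluded]
    if t.empty:
        raise ValueError(f"no usable rows for sequence {sequence}")
    d = pd.DataFrame({
        "rt_s": t.rt_s.to_numpy(),
        "x_cong": np.where(t.congruency == "incongruent", 0.5, -0.5),
        "participant": t.participant.to_numpy(),
        "word_length": t.word_length.to_numpy(),
    })
    d = pd.concat([d.reset_index(drop=True),
                   _position_contrasts(t.word_position.reset_index(drop=True))], axis=1)
    return d


ALL_MODELS = ("full", "no_congruency", "no_position")


def _run_lme4(frames: list[pd.DataFrame], models=ALL_MODELS) -> list[dict]:
    """Fit the model family for each design frame in one R session."""
    stacked = pd.concat(
        [f.assign(dataset=i) for i, f in enumerate(frames)], ignore_index=True
    )
    with tempfile.TemporaryDirectory() as td:
        csv_path = Path(td) / "rts.csv"
        out_path = Path(td) / "fits.json"
        script = Path(td) / "fit.R"
        stacked.to_csv(csv_path, index=False)
        script.write_text(_R_TEMPLATE)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(csv_path), str(out_path),
             ",".join(models)],
            capture_output=True, text=True, timeout=3600,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise RuntimeError(f"lme4 fitting failed:\n{proc.stderr[-2000:]}")
        return [json.loads(out_path.read_text())[str(i)] for i in range(len(frames))]


def _to_fit(raw: dict, sequence: str) -> GlmmFit:
    if "error" in raw:
        return GlmmFit(
            model=raw["model"], sequence=sequence, coef={}, se={}, random_sd={},
            loglik=np.nan, n_params=0, n_obs=0, converged=False,
            messages=[raw["error"]],
        )
    msgs = raw.get("messages", [])
    fit = GlmmFit(
        model=raw["model"], sequence=sequence,
        coef=dict(raw["coef"]),
        se=dict(zip(raw["coef"].keys(), raw["se"].values())),
        random_sd=dict(raw["random_sd"]),
        loglik=float(raw["loglik"]),
        n_params=int(raw["n_params"]),
        n_obs=int(raw["n_obs"]),
        converged=bool(raw["converged"]),
        messages=list(msgs) if isinstance(msgs, list) else [msgs],
    )
    if "x_cong" in fit.coef:
        fit.predicted_rt = fit.predict_means()
    return fit


def fit_rt_glmm_family(table: pd.DataFrame, sequence: str) -> dict:
    """Fit the full model and both nested reductions in one R session.

    Returns ``{'full': GlmmFit, 'no_congruency': GlmmFit,
    'no_position': GlmmFit}``.
    """
    raws = _run_lme4([_design_frame(table, sequence)])[0]
    return {r["model"]: _to_fit(r, sequence) for r in raws}


def fit_rt_glmm(table: pd.DataFrame, sequence: str) -> GlmmFit:
    """The full gamma GLMM (congruency + word position, random
    intercepts for participant and word length) for one sequence."""
    return fit_rt_glmm_family(table, sequence)["full"]


def fit_rt_glmm_batch(
    tables: list[pd.DataFrame], sequence: str, models=ALL_MODELS
) -> list[dict]:
    """Fit the model family for many replicate tables in one R session."""
    frames = [_design_frame(t, sequence) for t in tables]
    out = _run_lme4(frames, models)
    return [{r["model"]: _to_fit(r, sequence) for r in raws} for raws in out]


def lrt(full: GlmmFit, reduced: GlmmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested gamma GLMMs: (chi2, df, p)."""
    if reduced.n_params > full.n_params:
        raise ValueError("reduced model must be nested in the full model")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = int(full.n_params - reduced.n_params)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def congruency_lrt(table: pd.DataFrame, sequence: str) -> dict:
    """Congruency and word-position LRTs for one sequence, one R call."""
    fits = fit_rt_glmm_family(table, sequence)
    out = {"fits": fits}
    if fits["full"].converged or np.isfinite(fits["full"].loglik):
        out["congruency"] = lrt(fits["full"], fits["no_congruency"])
        out["word_position"] = lrt(fits["full"], fits["no_position"])
    return out
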