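"""Cohort-level pipeline: hyperparameter selection, leave-one-subject-out
(LOSO) validation, biomarker feature tables, linear-discriminant separation
and 2x2 condition-by-group statistics.

The biomarkers mirror the two scatter planes of the source analysis: the
log10 VLF (< 0.03 Hz) spectral powers of the first-order BP and CO2 kernels,
and the ANF gains of the 3rd and 4th global BP dynamic modes.  Global PDMs
are extracted per treatment arm; for subject-level gains they are derived
from the other N-1 subjects (LOSO), so each subject's features never use
that subject's own kernels for the mode shapes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anf import PDMANFModel, pdm_filter_outputs
from .laguerre import (IdentifiabilityWarning, LaguerreVolterraModel,
                       count_free_parameters)
from .pdm import assemble_kernel_matrix, extract_global_pdms
from .preprocess import preprocess_recording
from .series import GROUPS, SubjectRecording
from .spectra import (DEFAULT_NFFT, VLF_BAND, band_average_power,
                      kernel2_magnitude_spectrum, kernel_power_spectrum)

__all__ = [
    "KernelEntry",
    "SeparationResult",
    "estimate_cohort_kernels",
    "group_global_pdms",
    "loso_evaluate",
    "build_feature_table",
    "linear_separation",
    "paired_and_interaction_tests",
    "bic_select",
    "ModelSelectionResult",
    "run_study",
    "StudyResults",
    "GAIN_FEATURE_PAIR",
    "VLF_FEATURE_PAIR",
]

logger = logging.getLogger(__name__)

GAIN_FEATURE_PAIR = ("gain_pdm3_bp", "gain_pdm4_bp")
VLF_FEATURE_PAIR = ("kP_vlf_logpower", "kC_vlf_logpower")


@dataclass
class KernelEntry:
    """Kernel-estimation output for one subject x condition."""

    recording: SubjectRecording      # analysis-ready (preprocessed) record
    results: object                  # LaguerreVolterraResults
    bp_sd: float
    co2_sd: float

    @property
    def key(self):
        return self.recording.key


def estimate_cohort_kernels(recordings, alpha: float = 0.5,
                            n_laguerre: int = 5, memory: int | None = None,
                            preprocess: bool = True,
                            **preprocess_kwargs) -> dict:
    """Estimate Laguerre-Volterra kernels for every recording.

    Returns ``{(subject_id, group, condition): KernelEntry}``.  The
    sub-5-samples-per-parameter warning is raised once rather than per
    recording.
    """
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("once", IdentifiabilityWarning)
        for rec in recordings:
            r = preprocess_recording(rec, **preprocess_kwargs) if preprocess else rec
            res = LaguerreVolterraModel.from_recording(
                r, alpha=alpha, n_laguerre=n_laguerre, memory=memory).fit()
            out[r.key] = KernelEntry(
                recording=r, results=res,
                bp_sd=float(np.std(r.bp.values - r.bp.values.mean())),
                co2_sd=float(np.std(r.co2.values - r.co2.values.mean())))
    return out


def _group_entries(kernels: dict, group: str, exclude_subject=None):
    entries = [e for e in kernels.values()
               if e.recording.group == group
               and e.recording.subject_id != exclude_subject]
    # stable order: subject then condition (pre before post)
    entries.sort(key=lambda e: (e.recording.subject_id,
                                e.recording.condition != "pre"))
    return entries


def group_global_pdms(kernels: dict, group: str, H: int = 5,
                      exclude_subject=None):
    """Global PDM sets (BP and CO2) for one arm from stacked kernels.

    ``exclude_subject`` implements the LOSO fold: both conditions of that
    subject are left out of the stack.
    """
    entries = _group_entries(kernels, group, exclude_subject)
    if not entries:
        raise ValueError(f"no kernel entries for group {group!r}")
    bp_sets = [(e.recording.subject_id, e.recording.condition,
                e.results.kernels, e.bp_sd) for e in entries]
    co2_sets = [(e.recording.subject_id, e.recording.condition,
                 e.results.kernels, e.co2_sd) for e in entries]
    pdms_bp = extract_global_pdms(assemble_kernel_matrix(bp_sets, "BP"), H)
    pdms_co2 = extract_global_pdms(assemble_kernel_matrix(co2_sets, "CO2"), H)
    return pdms_bp, pdms_co2


def loso_evaluate(kernels: dict, H: int = 5, anf_order: int = 3,
                  screen_level: float = 0.99) -> dict:
    """Leave-one-subject-out PDM/ANF evaluation.

    For each subject: global PDMs from the other N-1 subjects of the same
    arm (both conditions), then ANFs and gains fitted for the held-out
    subject's pre and post recordings with those PDMs.

    Returns ``{(subject_id, group, condition): PDMANFResults}``; the PDM
    sets of each fold are attached to the results as ``loso_pdms``.
    """
    out = {}
    for group in GROUPS:
        subjects = sorted({e.recording.subject_id for e in kernels.values()
                           if e.recording.group == group})
        if not subjects:
            continue
        if len(subjects) < 3:
            raise ValueError(f"LOSO needs >= 3 subjects per group "
                             f"({group}: {len(subjects)})")
        for sid in subjects:
            pdms_bp, pdms_co2 = group_global_pdms(
                kernels, group, H=H, exclude_subject=sid)
            for cond in ("pre", "post"):
                entry = kernels[(sid, group, cond)]
                rec = entry.recording
                u = pdm_filter_outputs(pdms_bp, pdms_co2, rec)
                res = PDMANFModel(rec.flow, u, order=anf_order,
                                  screen_level=screen_level).fit()
                res.loso_pdms = (pdms_bp, pdms_co2)
                out[(sid, group, cond)] = res
    return out


def build_feature_table(kernels: dict, anf_results: dict | None = None,
                        band=VLF_BAND, nfft: int = DEFAULT_NFFT
                        ) -> pd.DataFrame:
    """Per subject x condition biomarker table.

    Kernel-spectrum features: ``kP_vlf_logpower``, ``kC_vlf_logpower``
    (log10 mean power of the first-order kernels over ``band``) and the raw
    VLF band powers of the three second-order kernels.  When ``anf_results``
    is given, ANF gains ``gain_pdm{i}_{bp,co2}`` are appended.
    """
    rows = []
    for key, e in kernels.items():
        sid, group, cond = key
        fs = e.recording.fs
        kn = e.results.kernels
        row = {"subject_id": sid, "group": group, "condition": cond}
        for name, k1 in (("kP", kn.kP), ("kC", kn.kC)):
            spec = kernel_power_spectrum(k1, fs=fs, nfft=nfft)
            feat = band_average_power(spec, *band)
            row[f"{name}_vlf_logpower"] = feat.log10_mean_power
        for name, k2 in (("kPP", kn.kPP), ("kCC", kn.kCC), ("kPC", kn.kPC)):
            s2 = kernel2_magnitude_spectrum(k2, fs=fs, nfft=nfft, band=band)
            row[f"{name}_vlf_power"] = s2.band_mean_power
        if anf_results is not None:
            if key not in anf_results:
                raise ValueError(f"missing ANF results for {key}")
            ar = anf_results[key]
            for i in range(ar.gains_bp.size):
                row[f"gain_pdm{i + 1}_bp"] = float(ar.gains_bp[i])
                row[f"gain_pdm{i + 1}_co2"] = float(ar.gains_co2[i])
            row["anf_nmse"] = ar.nmse
        row["kernel_nmse"] = e.results.nmse
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["group", "subject_id", "condition"],
        ascending=[True, True, False]).reset_index(drop=True)
    return df


@dataclass
class SeparationResult:
    """Fisher-discriminant separation of pre vs. post within one arm."""

    group: str
    features: tuple
    weights: np.ndarray
    threshold: float
    margins: np.ndarray        # signed margin per point (> 0 iff correct)
    accuracy: float
    complete_separation: bool
    fallback_mean_difference: bool = False


def linear_separation(table: pd.DataFrame, features=GAIN_FEATURE_PAIR,
                      group: str = "sympathetic") -> SeparationResult:
    """Fisher's linear discriminant on two features, classes pre vs. post.

    A singular within-class scatter falls back to the class-mean-difference
    direction (logged).  ``complete_separation`` is true iff every point is
    on the correct side of the midpoint threshold.
    """
    sub = table[table["group"] == group]
    X = sub[list(features)].to_numpy(float)
    y = (sub["condition"] == "post").to_numpy()
    if min(y.sum(), (~y).sum()) < 2:
        raise ValueError("need at least 2 points per class")
    m0, m1 = X[~y].mean(axis=0), X[y].mean(axis=0)
    Sw = (np.cov(X[~y].T, bias=False) * (np.sum(~y) - 1)
          + np.cov(X[y].T, bias=False) * (np.sum(y) - 1))
    fallback = False
    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > 1e12:
        logger.warning("singular within-class scatter for %s/%s; using "
                       "mean-difference direction", group, features)
        w = m1 - m0
        fallback = True
    else:
        w = np.linalg.solve(Sw, m1 - m0)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("identical class means: no discriminant direction")
    w = w / nw
    c = float(w @ (m0 + m1) / 2.0)
    proj = X @ w - c
    margins = np.where(y, proj, -proj)
    accuracy = float(np.mean(margins > 0))
    return SeparationResult(
        group=group, features=tuple(features), weights=w, threshold=c,
        margins=margins, accuracy=accuracy,
        complete_separation=bool(np.all(margins > 0)),
        fallback_mean_difference=fallback)


def paired_and_interaction_tests(table: pd.DataFrame, feature: str) -> dict:
    """Paired t-tests within each arm plus the condition-by-group
    interaction as a difference-in-differences two-sample t-test.

    For the balanced two-condition, two-group repeated design the
    two-sample t on per-subject (post - pre) differences is the exact
    interaction contrast.
    """
    diffs = {}
    out = {"feature": feature}
    for group in GROUPS:
        sub = table[table["group"] == group]
        piv = sub.pivot_table(index="subject_id", columns="condition",
                              values=feature)
        if piv.shape[0] < 3 or piv.isna().any().any():
            raise ValueError(f"need >= 3 complete pre/post pairs for {group}")
        pre = piv["pre"].to_numpy(float)
        post = piv["post"].to_numpy(float)
        if np.allclose(pre, post):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(post, pre)
        diffs[group] = post - pre
        out[f"paired_t_{group}"] = float(t)
        out[f"paired_p_{group}"] = float(p)
    d_s, d_p = diffs["sympathetic"], diffs["placebo"]
    if np.allclose(d_s.mean(), d_p.mean()) and np.allclose(
            np.concatenate([d_s, d_p]).std(), 0):
        t_i, p_i = 0.0, 1.0
    else:
        t_i, p_i = stats.ttest_ind(d_s, d_p, equal_var=True)
    out["interaction_t"] = float(t_i)
    out["interaction_p"] = float(p_i)
    return out


@dataclass
class ModelSelectionResult:
    grid: list
    bic: list
    chosen: tuple

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.grid,
                          columns=["alpha", "L", "H", "anf_order"])
        df["bic"] = self.bic
        return df


def bic_select(recordings, grid, preprocess: bool = True,
               screen_level: float = 0.99) -> ModelSelectionResult:
    """Cohort-wide BIC over a grid of (alpha, L, H, anf_order).

    Per recording, ``BIC = n ln(RSS/n) + k ln(n)`` with ``n`` the
    post-burn-in sample count, RSS from the subject-level PDM/ANF
    regression, and ``k`` the total per-subject free-parameter count
    (kernel expansion plus ANF regression); summed over recordings.
    Unidentifiable grid points are skipped with a log record; ties break
    toward smaller k.
    """
    evaluated, bics, complexity = [], [], []
    preprocessed = None
    for point in grid:
        alpha, L, H, order = point
        try:
            if preprocessed is None:
                kernels = estimate_cohort_kernels(
                    recordings, alpha=alpha, n_laguerre=L,
                    preprocess=preprocess)
                preprocessed = [e.recording for e in kernels.values()]
            else:
                kernels = estimate_cohort_kernels(
                    preprocessed, alpha=alpha, n_laguerre=L,
                    preprocess=False)
            total, k_total = 0.0, 0
            pdm_cache = {
                g: group_global_pdms(kernels, g, H=H)
                for g in GROUPS
                if any(e.recording.group == g for e in kernels.values())}
            for e in kernels.values():
                rec = e.recording
                pdms_bp, pdms_co2 = pdm_cache[rec.group]
                u = pdm_filter_outputs(pdms_bp, pdms_co2, rec)
                res = PDMANFModel(rec.flow, u, order=order,
                                  screen_level=screen_level).fit()
                n = res.resid.size
                k = count_free_parameters(L) + res.model.k_params
                total += n * np.log(res.rss / n) + k * np.log(n)
                k_total += k
            evaluated.append(point)
            bics.append(float(total))
            complexity.append(k_total)
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.info("grid point %s skipped: %s", point, err)
    if not evaluated:
        raise ValueError("no identifiable grid point")
    order_idx = sorted(range(len(evaluated)),
                       key=lambda i: (bics[i], complexity[i]))
    return ModelSelectionResult(grid=evaluated, bic=bics,
                                chosen=tuple(evaluated[order_idx[0]]))


@dataclass
class StudyResults:
    """End-to-end outputs of the biomarker pipeline on one cohort."""

    kernels: dict
    pdms: dict                       # group -> (GlobalPDMSet bp, co2)
    anf_results: dict                # LOSO-based, per subject x condition
    feature_table: pd.DataFrame
    separations: dict                # (group, features) -> SeparationResult
    statistics: list = field(default_factory=list)
    hyperparameters: dict = field(default_factory=dict)

    def summary(self) -> str:
        hp = self.hyperparameters
        lines = [
            "Cerebral-hemodynamics PDM biomarker study",
            "=" * 52,
            f"recordings analyzed:   {len(self.kernels)}",
            "hyperparameters:       "
            f"alpha={hp.get('alpha')}, L={hp.get('n_laguerre')}, "
            f"M={hp.get('memory')}, H={hp.get('H')}, "
            f"ANF order={hp.get('anf_order')}",
            f"VLF band:              {hp.get('band')} Hz "
            f"(nfft={hp.get('nfft')})",
            "",
            "pre/post separation (Fisher LDA):",
        ]
        for (group, feats), sep in self.separations.items():
            lines.append(
                f"  {group:<12} {'+'.join(feats):<40} "
                f"accuracy={sep.accuracy:.3f} "
                f"complete={sep.complete_separation}")
        if self.statistics:
            lines.append("")
            lines.append("paired / interaction tests:")
            for st in self.statistics:
                lines.append(
                    f"  {st['feature']:<22} "
                    f"t_symp={st['paired_t_sympathetic']:+.2f} "
                    f"(p={st['paired_p_sympathetic']:.2g})  "
                    f"t_plac={st['paired_t_placebo']:+.2f} "
                    f"(p={st['paired_p_placebo']:.2g})  "
                    f"interaction t={st['interaction_t']:+.2f} "
                    f"(p={st['interaction_p']:.2g})")
        return "\n".join(lines)


def run_study(recordings, alpha: float = 0.5, n_laguerre: int = 5,
              memory: int | None = None, H: int = 5, anf_order: int = 3,
              band=VLF_BAND, nfft: int = DEFAULT_NFFT,
              preprocess: bool = True,
              screen_level: float = 0.99) -> StudyResults:
    """Full pipeline: kernels -> spectra features -> group PDMs -> LOSO
    ANF gains -> feature table -> separation and 2x2 statistics."""
    kernels = estimate_cohort_kernels(
        recordings, alpha=alpha, n_laguerre=n_laguerre, memory=memory,
        preprocess=preprocess)
    groups = [g for g in GROUPS
              if any(e.recording.group == g for e in kernels.values())]
    pdms = {g: group_global_pdms(kernels, g, H=H) for g in groups}
    anf_results = loso_evaluate(kernels, H=H, anf_order=anf_order,
                                screen_level=screen_level)
    table = build_feature_table(kernels, anf_results, band=band, nfft=nfft)
    separations = {}
    stats_rows = []
    for g in groups:
        for feats in (VLF_FEATURE_PAIR, GAIN_FEATURE_PAIR):
            separations[(g, feats)] = linear_separation(table, feats, g)
    if set(groups) == set(GROUPS):
        for feature in (*VLF_FEATURE_PAIR, *GAIN_FEATURE_PAIR):
            stats_rows.append(paired_and_interaction_tests(table, feature))
    some_entry = next(iter(kernels.values()))
    return StudyResults(
        kernels=kernels, pdms=pdms, anf_results=anf_results,
        feature_table=table, separations=separations,
        statistics=stats_rows,
        hyperparameters={
            "alpha": alpha, "n_laguerre": n_laguerre,
            "memory": some_entry.results.model.basis.M, "H": H,
            "anf_order": anf_order, "band": tuple(band), "nfft": nfft,
            "screen_level": screen_level, "preprocess": preprocess,
        })
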