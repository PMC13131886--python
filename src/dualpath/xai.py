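"""Attribution and temporal-interpretation chain.

Integrated Gradients (IG) on the model input for each branch, attention-based
discriminative-event detection, attention-IG concordance, top-5% ROI
selection, the core presence matrix across events, subject-level saliency
indices, and maximal-overlap ROI -> network assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nn.model import DualPathClassifier, TrainedDualPath


@dataclass
class AttributionBundle:
    """Per-subject attribution products.

    ``ig_time_resolved`` is the signed IG map on the input (R x T, MIL-path
    target by default); ``ig_pooled`` is the global-branch attribution summed
    over time (length R); ``attention`` the MIL attention weights (length T).
    """

    subject_id: str
    ig_time_resolved: np.ndarray
    ig_pooled: np.ndarray
    attention: np.ndarray
    baseline_spec: str = "zeros"
    n_steps: int = 64


@dataclass
class EventWindow:
    """Half-open [start_tr, end_tr) window of significant group difference."""

    index: int
    start_tr: int
    end_tr: int
    test_statistic: float
    p_value: float
    direction: str  # "case" or "control": whose mean attention is higher

    def __post_init__(self) -> None:
        if self.start_tr >= self.end_tr:
            raise ValueError("start < end required")


@dataclass
class CorePresenceMatrix:
    matrix: pd.DataFrame           # R x E booleans
    threshold: int
    core_regions: list
    event_specific_regions: dict


@dataclass
class SaliencyIndices:
    subject_id: str
    global_index: float
    event_indices: np.ndarray


def integrated_gradients(
    model: DualPathClassifier | TrainedDualPath,
    x: np.ndarray,
    metadata: np.ndarray,
    target: int,
    baseline: np.ndarray | None = None,
    n_steps: int = 64,
    branch: str = "fused",
) -> np.ndarray:
    """IG on one subject's input: midpoint quadrature along the straight path
    from baseline to input, scaled by (input - baseline).

    Satisfies completeness: attributions sum to F(input) - F(baseline) for
    the chosen branch logit (metadata held fixed along the path).
    """
    if isinstance(model, TrainedDualPath):
        model = model.build()
    x = np.asarray(x, dtype=np.float32)
    if baseline is None:
        baseline = np.zeros_like(x)
    baseline = np.asarray(baseline, dtype=np.float32)
    if baseline.shape != x.shape:
        raise ValueError("baseline must match input shape")
    if n_steps < 8:
        warnings.warn("n_steps < 8: the completeness property may fail")
    alphas = ((np.arange(n_steps) + 0.5) / n_steps).astype(np.float32)
    path = baseline[None] + alphas[:, None, None] * (x - baseline)[None]
    meta = np.repeat(np.asarray(metadata, dtype=np.float32)[None], n_steps, axis=0)
    grads = model.input_gradient(path, meta, target=target, branch=branch)
    return (grads.mean(axis=0) * (x - baseline)).astype(np.float64)


def branch_output(model: DualPathClassifier, x: np.ndarray, metadata: np.ndarray,
                  target: int, branch: str = "fused") -> float:
    out = model.forward(x[None].astype(np.float32),
                        np.asarray(metadata, dtype=np.float32)[None])
    key = {"fused": "fused", "global": "global", "mil": "mil"}[branch]
    return float(out[key][0, target])


def compute_bundles(
    trained: TrainedDualPath,
    X: np.ndarray,
    meta: np.ndarray,
    subject_ids: list[str],
    n_steps: int = 32,
    baseline: np.ndarray | None = None,
) -> list[AttributionBundle]:
    """Attribution bundle for every subject, targeting the predicted class.

    The time-resolved map attributes the MIL-branch logit; the pooled map
    attributes the global-branch logit, summed over time.
    """
    model = trained.build()
    preds = []
    for i in range(0, len(X), 64):
        preds.append(model.predict(X[i:i + 64], meta[i:i + 64]))
    preds = np.concatenate(preds)
    bundles = []
    for i, sid in enumerate(subject_ids):
        base = baseline if baseline is not None else np.zeros_like(X[i])
        ig_t = integrated_gradients(model, X[i], meta[i], int(preds[i]),
                                    baseline=base, n_steps=n_steps, branch="mil")
        ig_g = integrated_gradients(model, X[i], meta[i], int(preds[i]),
                                    baseline=base, n_steps=n_steps, branch="global")
        attn = model.forward(X[i:i + 1], meta[i:i + 1])["attention"][0]
        bundles.append(AttributionBundle(
            subject_id=sid,
            ig_time_resolved=ig_t,
            ig_pooled=ig_g.sum(axis=1),
            attention=attn.astype(np.float64),
            baseline_spec="zeros" if baseline is None else "custom",
            n_steps=n_steps,
        ))
    return bundles


def ensemble_bundles(
    trained_models: list[TrainedDualPath],
    X: np.ndarray,
    meta: np.ndarray,
    subject_ids: list[str],
    n_steps: int = 32,
    baseline: np.ndarray | None = None,
) -> list[AttributionBundle]:
    """Attribution magnitudes averaged over an ensemble of fitted models.

    Redundant discriminative signals make single-fit attribution maps
    unstable (whichever signal a particular fit latched onto dominates);
    averaging |IG| and the attention profile over independently seeded fits
    yields robust group-level maps.  The returned bundles hold magnitude
    maps (nonnegative), which is what every downstream consumer uses.
    """
    if not trained_models:
        raise ValueError("need at least one trained model")
    per_model = [compute_bundles(tm, X, meta, subject_ids, n_steps=n_steps,
                                 baseline=baseline) for tm in trained_models]
    out = []
    for i, sid in enumerate(subject_ids):
        ig_t = np.mean([np.abs(bs[i].ig_time_resolved) for bs in per_model], axis=0)
        ig_p = np.mean([np.abs(bs[i].ig_pooled) for bs in per_model], axis=0)
        attn = np.mean([bs[i].attention for bs in per_model], axis=0)
        out.append(AttributionBundle(sid, ig_t, ig_p, attn,
                                     baseline_spec=per_model[0][i].baseline_spec,
                                     n_steps=n_steps))
    return out


def group_pooled_ig(bundles: list[AttributionBundle],
                    group_mask: np.ndarray) -> dict[str, np.ndarray]:
    """Per-ROI mean absolute pooled IG: per group and overall."""
    group_mask = np.asarray(group_mask, dtype=bool)
    pooled = np.stack([np.abs(b.ig_pooled) for b in bundles])
    if group_mask.sum() < 2 or (~group_mask).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    return {
        "case": pooled[group_mask].mean(axis=0),
        "control": pooled[~group_mask].mean(axis=0),
        "overall": pooled.mean(axis=0),
    }


def top_k_rois(scores: np.ndarray, fraction: float = 0.05) -> list[int]:
    """Indices of the k = round(fraction * R) largest scores (round-half-even);
    ties broken toward the smaller region index."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    R = len(scores)
    k = max(1, int(np.round(fraction * R)))
    if np.all(scores == 0):
        warnings.warn("all-zero scores: returning the k lowest-index regions")
    # stable sort on (-score, index) makes tie-breaking deterministic
    order = np.lexsort((np.arange(R), -scores))
    return sorted(order[:k].tolist())


def detect_events(
    attention_case: np.ndarray,
    attention_control: np.ndarray,
    alpha: float = 0.05,
    min_len: int = 3,
    correction: str | None = None,
) -> list[EventWindow]:
    """Windows where the groups' attention distributions differ.

    Per-timepoint two-sample Mann-Whitney rank test; timepoints with
    p < alpha are merged into maximal runs and runs shorter than ``min_len``
    dropped.  ``correction='bh'`` applies Benjamini-Hochberg across
    timepoints first.
    """
    A = np.asarray(attention_case, dtype=float)
    B = np.asarray(attention_control, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share T")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    T = A.shape[1]
    if alpha >= 1.0:
        stat = float("nan")
        return [EventWindow(1, 0, T, stat, 1.0,
                            "case" if A.mean() >= B.mean() else "control")]
    res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    stats_u = np.asarray(res.statistic, dtype=float)
    if correction == "bh":
        pvals = stats.false_discovery_control(pvals, method="bh")
    sig = pvals < alpha
    windows: list[EventWindow] = []
    t = 0
    while t < T:
        if sig[t]:
            start = t
            while t < T and sig[t]:
                t += 1
            if t - start >= min_len:
                sl = slice(start, t)
                direction = ("case" if A[:, sl].mean() >= B[:, sl].mean()
                             else "control")
                windows.append(EventWindow(
                    index=len(windows) + 1,
                    start_tr=start, end_tr=t,
                    test_statistic=float(stats_u[sl].mean()),
                    p_value=float(pvals[sl].min()),
                    direction=direction,
                ))
        else:
            t += 1
    return windows


def attention_ig_concordance(bundles: list[AttributionBundle],
                             group_mask: np.ndarray) -> dict[str, tuple[float, float]]:
    """Pearson r between group-mean attention and group-mean |IG|(t)."""
    group_mask = np.asarray(group_mask, dtype=bool)
    out = {}
    for name, mask in (("case", group_mask), ("control", ~group_mask)):
        sel = [b for b, m in zip(bundles, mask) if m]
        A = np.stack([b.attention for b in sel]).mean(axis=0)
        G = np.stack([np.abs(b.ig_time_resolved).mean(axis=0) for b in sel]).mean(axis=0)
        if len(A) < 3:
            raise ValueError("need T >= 3")
        if A.std() == 0 or G.std() == 0:
            raise ValueError("zero-variance series")
        r, p = stats.pearsonr(A, G)
        out[name] = (float(r), float(p))
    return out


def event_top_rois(bundles: list[AttributionBundle], window: EventWindow,
                   fraction: float = 0.05) -> list[int]:
    """Top-fraction ROIs by mean-over-subjects of the median |IG| within the
    event window."""
    if window.end_tr - window.start_tr < 1:
        raise ValueError("window shorter than 1 TR")
    sl = slice(window.start_tr, window.end_tr)
    scores = np.stack([
        np.median(np.abs(b.ig_time_resolved[:, sl]), axis=1) for b in bundles
    ]).mean(axis=0)
    return top_k_rois(scores, fraction)


def core_presence(event_sets: list[list[int]], n_regions: int,
                  threshold: int, region_ids: list[str] | None = None) -> CorePresenceMatrix:
    """Recurrence of top-contributing regions across events.

    Core regions appear in >= threshold events; event-specific regions in
    exactly one.
    """
    E = len(event_sets)
    if threshold > E:
        raise ValueError("threshold exceeds number of events")
    ids = region_ids or [f"ROI{i + 1:03d}" for i in range(n_regions)]
    mat = np.zeros((n_regions, E), dtype=bool)
    for e, regions in enumerate(event_sets):
        mat[list(regions), e] = True
    counts = mat.sum(axis=1)
    core = [ids[i] for i in np.flatnonzero(counts >= threshold)]
    specific = {f"E{e + 1}": [ids[i] for i in np.flatnonzero(mat[:, e] & (counts == 1))]
                for e in range(E)}
    df = pd.DataFrame(mat, index=ids, columns=[f"E{e + 1}" for e in range(E)])
    return CorePresenceMatrix(df, threshold, core, specific)


def saliency_indices(
    bundles: list[AttributionBundle],
    global_set: list[int],
    event_sets: list[list[int]],
    windows: list[EventWindow],
) -> list[SaliencyIndices]:
    """Subject-level neural saliency: mean |IG| over the chosen region set
    (and, for events, the event's time window)."""
    if not global_set or any(not s for s in event_sets):
        raise ValueError("region sets must be nonempty")
    out = []
    for b in bundles:
        g = float(np.abs(b.ig_pooled[list(global_set)]).mean())
        ev = np.array([
            float(np.abs(b.ig_time_resolved[np.ix_(list(s), range(w.start_tr, w.end_tr))]).mean())
            for s, w in zip(event_sets, windows)
        ])
        out.append(SaliencyIndices(b.subject_id, g, ev))
    return out


def indices_frame(indices: list[SaliencyIndices]) -> pd.DataFrame:
    rows = []
    for s in indices:
        row = {"subject_id": s.subject_id, "global_index": s.global_index}
        row.update({f"E{e + 1}": v for e, v in enumerate(s.event_indices)})
        rows.append(row)
    return pd.DataFrame(rows)


def assign_networks(roi_labels: np.ndarray, network_labels: np.ndarray) -> pd.DataFrame:
    """Maximal-overlap assignment of atlas ROIs to network parcels.

    Both arrays live on the same voxel grid with 0 = background.  Each ROI
    goes to the network covering the largest fraction of its voxels; exact
    ties break to the lower network id with a flag; ROIs overlapping no
    network are 'unassigned'.
    """
    roi = np.asarray(roi_labels).ravel()
    net = np.asarray(network_labels).ravel()
    if roi.shape != net.shape:
        raise ValueError("label arrays must be congruent")
    rows = []
    for r in np.unique(roi):
        if r == 0:
            continue
        inside = net[roi == r]
        n_vox = len(inside)
        nets, counts = np.unique(inside[inside > 0], return_counts=True)
        if len(nets) == 0:
            rows.append({"region_id": int(r), "network": "unassigned",
                         "proportion": 0.0, "tie": False})
            continue
        best = counts.max()
        winners = nets[counts == best]
        rows.append({
            "region_id": int(r),
            "network": int(winners.min()),
            "proportion": float(best / n_vox),
            "tie": bool(len(winners) > 1),
        })
    return pd.DataFrame(rows)


def events_frame(windows: list[EventWindow], run_name: str = "run") -> pd.DataFrame:
    """BED-like 0-based half-open interval table for detected events."""
    return pd.DataFrame([{
        "run": run_name, "start_tr": w.start_tr, "end_tr": w.end_tr,
        "event": f"E{w.index}", "statistic": w.test_statistic,
        "p_value": w.p_value, "direction": w.direction,
    } for w in windows])
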