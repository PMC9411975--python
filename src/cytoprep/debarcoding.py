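"""Single-cell debarcoding (deconvolution of mass-tag multiplexed samples).

Samples pooled for acquisition are labeled with binary palladium mass-tag
barcodes.  Deconvolution proceeds in three steps:

1. preliminary assignment — each event's ``k`` highest barcode-channel
   intensities are declared positive and the induced binary word is matched
   against the barcoding key (:func:`assign_prelim`);
2. automated estimation of per-barcode separation cutoffs from
   yield-versus-cutoff curves (:func:`est_cutoffs`);
3. application of the cutoffs, plus a Mahalanobis-distance outlier trim,
   to arrive at final assignments (:func:`apply_cutoffs`).

Events that cannot be assigned confidently carry barcode ID ``"0"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .frame import CytofFrame

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodingScheme",
    "DebarcodingResult",
    "read_scheme",
    "assign_prelim",
    "compute_yields",
    "est_cutoffs",
    "apply_cutoffs",
]

UNASSIGNED = "0"


@dataclass
class BarcodingScheme:
    """Binary barcoding key B in {0,1}^(n x m).

    Rows are barcodes (samples), columns are barcode-channel masses.
    ``key.loc[i, j] == 1`` means barcode ``i`` is positive for the channel
    measuring mass ``j``.
    """

    key: pd.DataFrame  # index: barcode ids (str), columns: masses (int), values 0/1

    def __post_init__(self) -> None:
        key = self.key
        vals = key.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("barcoding key entries must be 0 or 1")
        if (vals.sum(axis=1) == 0).any():
            bad = key.index[vals.sum(axis=1) == 0].tolist()
            raise ValueError(f"all-zero barcode rows: {bad}")
        if key.duplicated().any():
            dup = key.index[key.duplicated(keep=False)].tolist()
            raise ValueError(f"duplicate barcode rows: {dup}")
        self.key = key.astype(int)
        self.key.columns = [int(c) for c in key.columns]

    @property
    def barcode_ids(self) -> list[str]:
        return [str(i) for i in self.key.index]

    @property
    def channel_masses(self) -> list[int]:
        return list(self.key.columns)

    @property
    def n(self) -> int:
        return self.key.shape[0]

    @property
    def m(self) -> int:
        return self.key.shape[1]

    @property
    def k_per_row(self) -> np.ndarray:
        return self.key.to_numpy().sum(axis=1)

    @property
    def is_constant_k(self) -> bool:
        return len(set(self.k_per_row)) == 1

    @property
    def k(self) -> int:
        if not self.is_constant_k:
            raise ValueError("scheme has non-constant row weights")
        return int(self.k_per_row[0])

    def drop_empty(self, pattern: str = "empty") -> "BarcodingScheme":
        """Remove placeholder barcodes (rows whose ID contains *pattern*)."""
        keep = [i for i in self.key.index if pattern not in str(i).lower()]
        return BarcodingScheme(self.key.loc[keep])

    def to_csv(self, path: str) -> None:
        self.key.to_csv(path)


def read_scheme(path: str | Path, remove_empty: bool = False) -> BarcodingScheme:
    """Read a debarcoding key CSV (row labels = barcode IDs, columns = masses)."""
    key = pd.read_csv(path, index_col=0)
    key.index = key.index.astype(str)
    scheme = BarcodingScheme(key)
    if remove_empty:
        scheme = scheme.drop_empty()
    return scheme


@dataclass
class DebarcodingResult:
    """Per-event assignments plus the quantities they were derived from."""

    scheme: BarcodingScheme
    assay: str
    bc_id: np.ndarray  # str per event; "0" = unassigned
    delta: np.ndarray  # separation in [0, 1]
    scaled: np.ndarray  # E x m quantile-scaled barcode intensities
    prelim_id: np.ndarray | None = None
    sep_cutoffs: pd.Series | None = None
    mhl_cutoff: float | None = None
    mhl: np.ndarray | None = None
    yields: pd.DataFrame | None = None
    cutoff_fits: pd.DataFrame | None = None

    @property
    def assigned(self) -> np.ndarray:
        return self.bc_id != UNASSIGNED


# ---------------------------------------------------------------------------
# preliminary assignment


def _scale_by_population(
    X: np.ndarray,
    ids: np.ndarray,
    pos_channels: dict[str, np.ndarray],
    q: float = 0.95,
) -> np.ndarray:
    """Scale each preliminary population to its positive-signal q-quantile.

    For every population the q-quantile of its positive barcode-channel
    intensities (pooled over that population's positive channels) is the
    scale factor for all of its barcode channels, bringing populations to a
    comparable scale while keeping negative channels small.  Populations
    with fewer than 2 events — and unassigned events — fall back to a
    global factor (the q-quantile of positive-channel signal over all
    assigned events).  Scaled values are clipped to [0, 1] so the
    separation is bounded.
    """
    pooled = [X[ids == pop][:, pos] for pop, pos in pos_channels.items()
              if (ids == pop).any()]
    if pooled and sum(p.size for p in pooled):
        global_q = float(np.quantile(np.concatenate([p.ravel() for p in pooled]), q))
    else:
        global_q = float(np.quantile(X, q)) if X.size else 1.0
    if global_q <= 0:
        global_q = 1.0
    scaled = np.empty_like(X, dtype=float)
    unseen = ~np.isin(ids, list(pos_channels))
    scaled[unseen] = X[unseen] / global_q
    for pop, pos in pos_channels.items():
        mask = ids == pop
        if not mask.any():
            continue
        if mask.sum() < 2:
            logger.warning("population %r has < 2 events; global quantile used", pop)
            qs = global_q
        else:
            qs = float(np.quantile(X[mask][:, pos], q))
            if qs <= 0:
                qs = global_q
        scaled[mask] = X[mask] / qs
    return np.clip(scaled, 0.0, 1.0)


def assign_prelim(
    frame: CytofFrame,
    scheme: BarcodingScheme,
    assay: str = "exprs",
    quantile: float = 0.95,
) -> DebarcodingResult:
    """Preliminary barcode assignment by each event's top-k barcode channels.

    The induced binary word is matched against the key; events whose word is
    absent from the key are unassigned.  Barcode-channel intensities are then
    scaled to each preliminary population's 95th percentile and the
    separation ``delta`` (lowest positive minus highest negative scaled
    intensity) is computed.  Annotates ``bc_id`` and ``delta`` on the frame.
    """
    if not scheme.is_constant_k:
        raise ValueError(
            "mixed-k barcoding schemes are not supported: all barcodes must be "
            "positive for the same number of channels"
        )
    if assay not in frame.assays:
        raise KeyError(f"assay {assay!r} not in frame; have {list(frame.assays)}")
    cols = frame.channel_indices(scheme.channel_masses)
    X = frame.assays[assay][:, cols]
    m, k = scheme.m, scheme.k

    # top-k word per event; stable argsort so ties break by channel order
    order = np.argsort(-X, axis=1, kind="stable")
    word = np.zeros(X.shape, dtype=int)
    np.put_along_axis(word, order[:, :k], 1, axis=1)

    powers = 1 << np.arange(m)
    codes = word @ powers
    key_codes = scheme.key.to_numpy() @ powers
    lookup = {c: i for i, c in enumerate(key_codes)}
    idx = np.array([lookup.get(c, -1) for c in codes])
    ids = np.array(scheme.barcode_ids + [UNASSIGNED], dtype=object)[idx]

    all_zero = ~(X > 0).any(axis=1)
    ids[all_zero] = UNASSIGNED

    pos_channels = {bc: scheme.key.loc[bc].to_numpy().astype(bool)
                    for bc in scheme.barcode_ids}
    scaled = _scale_by_population(X, ids, pos_channels, quantile)
    s_sorted = -np.sort(-scaled, axis=1, kind="stable")
    delta = s_sorted[:, k - 1] - s_sorted[:, k]
    delta = np.clip(delta, 0.0, 1.0)
    delta[all_zero] = 0.0

    frame.event_meta["bc_id"] = ids.astype(str)
    frame.event_meta["delta"] = delta
    frame.channel_meta["is_bc"] = [i in cols for i in range(frame.n_channels)]
    n_un = int((ids == UNASSIGNED).sum())
    frame.log(
        f"assign_prelim(assay={assay!r}): {n_un}/{len(ids)} events "
        f"({100 * n_un / max(len(ids), 1):.2f}%) unassigned"
    )
    return DebarcodingResult(scheme, assay, ids.astype(str), delta, scaled,
                             prelim_id=ids.astype(str).copy())


def assign_by_key(X: np.ndarray, key: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign events to the row of an arbitrary binary key maximizing the
    separation min(positives) - max(negatives); returns (row index, scaled delta).

    Used internally (e.g. bead tagging during normalization) where row
    weights differ; the public debarcoding path requires constant k.
    """
    n, m = key.shape
    seps = np.empty((X.shape[0], n))
    for r in range(n):
        pos = key[r].astype(bool)
        lo = X[:, pos].min(axis=1) if pos.any() else np.zeros(X.shape[0])
        hi = X[:, ~pos].max(axis=1) if (~pos).any() else np.zeros(X.shape[0])
        seps[:, r] = lo - hi
    rows = np.argmax(seps, axis=1)
    # population-quantile scaling, then recompute delta per assigned row
    # (labels prefixed so no row collides with the "0" unassigned sentinel)
    ids = np.array([f"r{r}" for r in rows], dtype=object)
    pos_channels = {f"r{r}": key[r].astype(bool) for r in range(n)}
    scaled = _scale_by_population(X, ids, pos_channels)
    delta = np.empty(X.shape[0])
    for r in range(n):
        mask = rows == r
        if not mask.any():
            continue
        pos = key[r].astype(bool)
        lo = scaled[mask][:, pos].min(axis=1) if pos.any() else 0.0
        hi = scaled[mask][:, ~pos].max(axis=1) if (~pos).any() else 0.0
        delta[mask] = lo - hi
    return rows, np.clip(delta, 0.0, 1.0)


# ---------------------------------------------------------------------------
# yield curves and cutoff estimation


def compute_yields(
    result: DebarcodingResult, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-barcode cell yield as a function of the applied separation cutoff.

    ``yield(c, barcode)`` is the fraction of that barcode's preliminarily
    assigned events with ``delta >= c``; a non-increasing step function.
    """
    if grid is None:
        grid = np.round(np.arange(0, 1.01, 0.01), 2)
    grid = np.asarray(grid, dtype=float)
    out = {}
    for bc in result.scheme.barcode_ids:
        d = result.delta[result.bc_id == bc]
        if d.size == 0:
            out[bc] = np.zeros_like(grid)
        else:
            out[bc] = (d[None, :] >= grid[:, None]).mean(axis=1)
    yields = pd.DataFrame(out, index=grid)
    yields.index.name = "cutoff"
    result.yields = yields
    return yields


def separation_histogram(result: DebarcodingResult, bins: int = 100) -> pd.DataFrame:
    """Histogram of separations over all preliminarily assigned events."""
    counts, edges = np.histogram(result.delta[result.assigned], bins=bins, range=(0, 1))
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def _log_logistic(x: np.ndarray, b: float, e: float, d: float) -> np.ndarray:
    """Three-parameter log-logistic f(x) = d / (1 + exp(b (ln x - ln e)));
    lower asymptote 0, upper asymptote d, inflection e, slope b."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        z = np.where(x > 0, np.exp(np.clip(b * (np.log(np.where(x > 0, x, 1.0)) - np.log(e)),
                                           -700, 700)), 0.0)
    return d / (1.0 + z)


def _log_logistic_deriv(x: np.ndarray, b: float, e: float, d: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    f = _log_logistic(x, b, e, d)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        z = np.where(x > 0, np.exp(np.clip(b * (np.log(np.where(x > 0, x, 1.0)) - np.log(e)),
                                           -700, 700)), 0.0)
        deriv = np.where(x > 0, -d * b * z / (x * (1.0 + z) ** 2), 0.0)
    return deriv


def est_cutoffs(
    result: DebarcodingResult,
    frame: CytofFrame | None = None,
    criterion: str = "onset",
) -> pd.Series:
    """Estimate a separation cutoff per barcode from its yield curve.

    A linear model and a three-parameter log-logistic model are fitted to
    yield versus cutoff.  The linear estimate is the cutoff where the fitted
    yield declines to half the intercept, ``c_lin = -b0 / (2 b1)``.  The
    log-logistic estimate targets the end of the plateau regime — the point
    where the fitted curve's decline relative to its value becomes
    appreciable: the smallest grid cutoff with ``|f'(x)| / f(x) > 0.1``
    (``criterion="onset"``, the default).  Two alternative readings are
    switchable: ``"deriv"`` takes the argmin of |f'(x)| over grid points
    with ``f(x) > 0.1`` and ``"ratio"`` the argmin of |f'|/f on the same
    support.  The final cutoff is the mean of both estimates, weighted by
    relative goodness of fit: ``c = w c_lin + (1 - w) c_ll`` with
    ``w = RSS_ll / (RSS_ll + RSS_lin)``.

    Assignments are left unchanged; cutoffs are stored on the result (and on
    the frame's experiment metadata when a frame is given).
    """
    if result.yields is None:
        compute_yields(result)
    yields = result.yields
    grid = yields.index.to_numpy()
    cutoffs, rows = {}, []
    for bc in yields.columns:
        y = yields[bc].to_numpy()
        b1, b0 = np.polyfit(grid, y, 1)
        rss_lin = float(((np.polyval([b1, b0], grid) - y) ** 2).sum())
        c_lin = -b0 / (2.0 * b1) if b1 < 0 else np.nan

        c_ll, rss_ll, ll_params = np.nan, np.inf, None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p0 = (5.0, float(np.median(grid[grid > 0])), float(y.max()) or 1.0)
                popt, _ = curve_fit(_log_logistic, grid, y, p0=p0, maxfev=10000)
            fit = _log_logistic(grid, *popt)
            rss_ll = float(((fit - y) ** 2).sum())
            pos = grid > 0
            rel = np.abs(_log_logistic_deriv(grid[pos], *popt)) / np.maximum(fit[pos], 1e-12)
            if criterion == "onset":
                onset = rel > 0.1
                if onset.any():
                    c_ll = float(grid[pos][np.argmax(onset)])
            else:
                support = fit[pos] > 0.1
                if support.any():
                    obj = np.abs(_log_logistic_deriv(grid[pos][support], *popt))
                    if criterion == "ratio":
                        obj = obj / fit[pos][support]
                    c_ll = float(grid[pos][support][np.argmin(obj)])
            ll_params = popt
        except (RuntimeError, TypeError, ValueError):
            logger.warning("log-logistic fit failed for barcode %r; linear estimate used", bc)

        if b1 >= 0:
            # degenerate flat/rising yield curve: no decline to anchor on
            logger.warning("barcode %r has non-decreasing linear yield fit", bc)
            c = c_ll if np.isfinite(c_ll) else float(np.median(grid))
        elif not np.isfinite(c_ll):
            c = c_lin
        else:
            w = rss_ll / (rss_ll + rss_lin) if (rss_ll + rss_lin) > 0 else 0.0
            c = w * c_lin + (1.0 - w) * c_ll
        cutoffs[bc] = float(np.clip(c, grid[0], grid[-1]))
        rows.append({
            "bc_id": bc, "c_linear": c_lin, "c_log_logistic": c_ll,
            "rss_linear": rss_lin, "rss_log_logistic": rss_ll,
            "w": rss_ll / (rss_ll + rss_lin) if np.isfinite(rss_ll) and (rss_ll + rss_lin) > 0 else np.nan,
            "cutoff": cutoffs[bc],
        })
    sep = pd.Series(cutoffs, name="sep_cutoff")
    result.sep_cutoffs = sep
    result.cutoff_fits = pd.DataFrame(rows).set_index("bc_id")
    if frame is not None:
        frame.experiment_meta["sep_cutoffs"] = sep.to_dict()
        frame.log(f"est_cutoffs: estimated cutoffs for {len(sep)} barcodes "
                  f"(median {sep.median():.3f})")
    return sep


# ---------------------------------------------------------------------------
# final filtering


def _mahalanobis(X: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Mahalanobis distance of each row to the sample mean/covariance; the
    covariance is ridge-regularized when singular."""
    mu = X.mean(axis=0)
    Xc = X - mu
    cov = np.cov(Xc, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        lam = ridge * np.trace(cov) / cov.shape[0]
        logger.warning("singular covariance; ridge lambda=%g applied", lam)
        inv = np.linalg.inv(cov + lam * np.eye(cov.shape[0]))
    d2 = np.einsum("ij,jk,ik->i", Xc, inv, Xc)
    return np.sqrt(np.maximum(d2, 0.0))


def apply_cutoffs(
    result: DebarcodingResult,
    frame: CytofFrame | None = None,
    sep_cutoffs: float | pd.Series | dict | None = None,
    mhl_cutoff: float = 30.0,
) -> np.ndarray:
    """Apply separation and Mahalanobis cutoffs to finalize assignments.

    An event is unassigned when its separation falls below its barcode's
    cutoff, or when its Mahalanobis distance — computed from the mean and
    covariance of the scaled barcode intensities of its (separation-filtered)
    preliminary population — exceeds ``mhl_cutoff``.  ``sep_cutoffs`` may be
    a global scalar, a per-barcode mapping, or ``None`` to use the estimates
    stored by :func:`est_cutoffs`.
    """
    if sep_cutoffs is None:
        if result.sep_cutoffs is None:
            raise ValueError("no separation cutoffs: run est_cutoffs or pass sep_cutoffs")
        cut = result.sep_cutoffs
    elif np.isscalar(sep_cutoffs):
        cut = pd.Series(float(sep_cutoffs), index=result.scheme.barcode_ids)
    else:
        cut = pd.Series(sep_cutoffs).astype(float)

    base = result.prelim_id if result.prelim_id is not None else result.bc_id
    ids = base.astype(object).copy()
    for bc in result.scheme.barcode_ids:
        mask = (base == bc) & (result.delta < cut.get(bc, 0.0))
        ids[mask] = UNASSIGNED

    mhl = np.zeros(len(ids))
    m = result.scheme.m
    if np.isfinite(mhl_cutoff):
        for bc in result.scheme.barcode_ids:
            mask = ids == bc
            if mask.sum() <= m + 1:
                continue
            d = _mahalanobis(result.scaled[mask])
            mhl[mask] = d
            out = mask.copy()
            out[mask] = d > mhl_cutoff
            ids[out] = UNASSIGNED

    result.bc_id = ids.astype(str)
    result.mhl = mhl
    result.mhl_cutoff = float(mhl_cutoff)
    if frame is not None:
        frame.event_meta["bc_id"] = result.bc_id
        frame.event_meta["mhl"] = mhl
        n_un = int((result.bc_id == UNASSIGNED).sum())
        frame.log(f"apply_cutoffs(mhl_cutoff={mhl_cutoff}): "
                  f"{n_un}/{len(ids)} events unassigned")
    return result.bc_id
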