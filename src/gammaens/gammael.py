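"""Gamma-element detection and parameterization inside theta cycles.

A gamma element is a patch of locally elevated gamma power in the per-cycle
CSD spectrogram snippet (38 frequency rows x 36 theta-phase bins).  Patches
are found by scanning a decreasing amplitude threshold starting from the
snippet maximum: supra-threshold cells form 4-connected components, components
that would fuse as the threshold drops keep their pre-merge extents as
separate patches, and the scan stops once ``max_count`` (four) components are
identified, so each theta cycle contributes at most four elements.
Components touching the cycle boundary are resolved against the adjacent
cycles' snippets and assigned to the cycle holding the larger share of their
power, so no element is counted twice.

The threshold grid is the sorted set of distinct amplitude values, which makes
the sweep exact and parameter-free.  Internally the sweep is a
persistence-style union-find over cells visited in decreasing amplitude
order; cells of equal amplitude are processed as one batch, which is exactly
equivalent to binarizing at that threshold value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lfp import SPEC_FREQS
from .thetacycles import N_PHASE_BINS, ThetaCycle

MAX_ELEMENTS_PER_CYCLE = 4
MIN_PATCH_FREQ_HZ = 30.0  # rows below the gamma composite band do not seed patches


@dataclass
class GammaPatch:
    """A connected set of spectrogram cells forming one gamma element."""

    rows: np.ndarray          # frequency-row indices
    cols: np.ndarray          # phase-bin column indices (grid frame)
    amps: np.ndarray
    birth_threshold: float    # amplitude at which it was last counted separate
    col_offset: int = 0       # column holding phase-bin 0 of the home cycle

    @property
    def mean_amp(self) -> float:
        return float(self.amps.mean())

    def frequency(self, freqs: np.ndarray = SPEC_FREQS) -> float:
        """Power-weighted mean of cell center frequencies (Hz)."""
        w = self.amps / self.amps.sum()
        return float(np.sum(w * np.asarray(freqs)[self.rows]))

    def phase_deg(self) -> float:
        """Power-weighted circular mean of cell phase-bin centers (deg)."""
        centers = (self.cols - self.col_offset) * 10.0 + 5.0
        w = self.amps / self.amps.sum()
        z = np.sum(w * np.exp(1j * np.deg2rad(centers)))
        deg = float(np.rad2deg(np.angle(z)) % 360.0)
        return 0.0 if deg >= 360.0 else deg

    def power_share(self, lo_col: int, hi_col: int) -> float:
        m = (self.cols >= lo_col) & (self.cols < hi_col)
        return float(self.amps[m].sum())


class _Cluster:
    __slots__ = ("cells", "fusion", "birth", "pw")

    def __init__(self, cells: list[tuple[int, int]], fusion: bool, birth: float,
                 pw: np.ndarray):
        self.cells = cells
        self.fusion = fusion
        self.birth = birth
        self.pw = pw  # power in [before, inside, after] column segments


def _sweep(amp: np.ndarray, min_row: int, lo_col: int, hi_col: int,
           max_count: int):
    """Decreasing-threshold sweep with fusion tracking.

    Stops once ``max_count`` identified components (frozen pre-merge extents
    plus live non-fusion components) are assignable to the center column
    segment [lo_col, hi_col), i.e. hold at least as much power there as in
    either flank.  Returns (cells, birth, pw) records.
    """
    nr, nc = amp.shape
    comp = -np.ones((nr, nc), dtype=np.int64)
    clusters: dict[int, _Cluster] = {}
    frozen: list[tuple[list, float, np.ndarray]] = []
    next_id = 0

    rs, cs = np.nonzero(amp > 0)
    sel = rs >= min_row
    rs, cs = rs[sel], cs[sel]
    if len(rs) == 0:
        return []
    vals = amp[rs, cs]
    order = np.argsort(-vals, kind="stable")
    rs, cs, vals = rs[order], cs[order], vals[order]

    def seg(c: int) -> int:
        return 0 if c < lo_col else (1 if c < hi_col else 2)

    def assignable(pw: np.ndarray) -> bool:
        return pw[1] >= pw[0] and pw[1] >= pw[2] and pw[1] > 0

    def records():
        live = [(cl.cells, cl.birth, cl.pw)
                for cl in clusters.values() if not cl.fusion]
        return frozen + live

    i = 0
    n_cells = len(rs)
    while i < n_cells:
        v = vals[i]
        j = i
        while j < n_cells and vals[j] == v:
            j += 1
        batch = [(int(rs[k]), int(cs[k])) for k in range(i, j)]
        i = j
        batch_set = set(batch)

        # union-find over batch cells and adjacent prior clusters
        parent: dict = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for cell in batch:
            parent[cell] = cell
        for r, c in batch:
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (min_row <= rr < nr and 0 <= cc < nc):
                    continue
                if (rr, cc) in batch_set:
                    union((r, c), (rr, cc))
                else:
                    cid = comp[rr, cc]
                    if cid >= 0:
                        key = ("k", int(cid))
                        if key not in parent:
                            parent[key] = key
                        union((r, c), key)

        groups: dict = {}
        for node in parent:
            groups.setdefault(find(node), []).append(node)

        for members in groups.values():
            new_cells = [m for m in members if not isinstance(m[0], str)]
            prior_ids = [m[1] for m in members if isinstance(m[0], str)]
            pw = np.zeros(3)
            for r, c in new_cells:
                pw[seg(c)] += amp[r, c]
            if len(prior_ids) == 0:
                cl = _Cluster(new_cells, fusion=False, birth=float(v), pw=pw)
            elif len(prior_ids) == 1:
                old = clusters.pop(prior_ids[0])
                cl = _Cluster(old.cells + new_cells, fusion=old.fusion,
                              birth=old.birth, pw=old.pw + pw)
            else:
                all_cells = list(new_cells)
                for pid in prior_ids:
                    old = clusters.pop(pid)
                    if not old.fusion:
                        frozen.append((list(old.cells), old.birth, old.pw))
                    all_cells += old.cells
                    pw = pw + old.pw
                cl = _Cluster(all_cells, fusion=True, birth=float(v), pw=pw)
            clusters[next_id] = cl
            for r, c in cl.cells:
                comp[r, c] = next_id
            next_id += 1

        n_assignable = sum(1 for _, _, pw in frozen if assignable(pw))
        n_assignable += sum(1 for cl in clusters.values()
                            if not cl.fusion and assignable(cl.pw))
        if n_assignable >= max_count:
            break
    return records()


def _rank_key(patch: GammaPatch):
    """Deterministic strength ordering: mean amplitude, earlier phase, lower freq."""
    return (-patch.mean_amp, patch.phase_deg(), patch.frequency())


def _to_patch(cells: list, birth: float, amp: np.ndarray, col_offset: int) -> GammaPatch:
    rows = np.array([r for r, _ in cells], dtype=int)
    cols = np.array([c for _, c in cells], dtype=int)
    return GammaPatch(rows=rows, cols=cols, amps=amp[rows, cols],
                      birth_threshold=float(birth), col_offset=col_offset)


def _assignable(pw: np.ndarray) -> bool:
    return pw[1] >= pw[0] and pw[1] >= pw[2] and pw[1] > 0


def detect_patches(
    snippet: np.ndarray,
    neighbors: tuple[np.ndarray | None, np.ndarray | None] | None = None,
    max_count: int = MAX_ELEMENTS_PER_CYCLE,
    freqs: np.ndarray = SPEC_FREQS,
    min_freq_hz: float = MIN_PATCH_FREQ_HZ,
) -> list[GammaPatch]:
    """Detect at most ``max_count`` gamma patches in one cycle snippet.

    ``neighbors`` optionally holds the (previous, next) cycle snippets; when
    given, the sweep runs on the concatenated grid and boundary-straddling
    components are assigned to the cycle holding most of their power — only
    patches assigned to the center cycle are returned.  Rows whose center
    frequency is below ``min_freq_hz`` (sub-gamma) are excluded.
    """
    snippet = np.asarray(snippet, dtype=float)
    freqs = np.asarray(freqs, dtype=float)[: snippet.shape[0]]
    min_row = int(np.searchsorted(freqs, min_freq_hz))
    nc = snippet.shape[1]

    if neighbors is None:
        grid, offset = snippet, 0
        lo_col, hi_col = 0, nc
    else:
        prev, nxt = neighbors
        zeros = np.zeros_like(snippet)
        grid = np.hstack([prev if prev is not None else zeros,
                          snippet,
                          nxt if nxt is not None else zeros])
        offset = nc
        lo_col, hi_col = nc, 2 * nc

    records = _sweep(grid, min_row, lo_col, hi_col, max_count)
    patches = [_to_patch(cells, b, grid, offset)
               for cells, b, pw in records if _assignable(pw)]
    patches.sort(key=_rank_key)
    return patches[:max_count]


@dataclass
class GammaElement:
    """The six-feature parameterization of one gamma element plus provenance."""

    gamma_amplitude: float
    gamma_frequency: float
    gamma_phase: float
    theta_amplitude: float
    theta_frequency: float
    theta_asymmetry: float
    channel: int = -1
    layer: str = ""
    trial: int = -1
    cycle_id: int = -1
    section: str = ""
    section_alt: str = ""
    speed: float = np.nan

FEATURES = ["gamma_amplitude", "gamma_frequency", "gamma_phase",
            "theta_amplitude", "theta_frequency", "theta_asymmetry"]
GAMMA_FEATURES = FEATURES[:3]
THETA_FEATURES = FEATURES[3:]


def characterize_element(
    patch: GammaPatch, cycle: ThetaCycle,
    freqs: np.ndarray = SPEC_FREQS, **metadata,
) -> GammaElement:
    """Build the 6-feature element: 3 gamma features from the patch (mean
    amplitude, power-weighted frequency and circular phase) and 3 theta
    features copied from the host cycle."""
    return GammaElement(
        gamma_amplitude=patch.mean_amp,
        gamma_frequency=patch.frequency(freqs),
        gamma_phase=patch.phase_deg(),
        theta_amplitude=cycle.amplitude,
        theta_frequency=cycle.frequency,
        theta_asymmetry=cycle.asymmetry,
        **metadata,
    )


def compile_element_table(elements: list[GammaElement],
                          trim_pct: float = 1.0,
                          speed_cut: float = 100.0) -> pd.DataFrame:
    """Concatenate elements and apply the exclusion filters.

    Per trial and channel, elements in the top and bottom ``trim_pct`` percent
    of gamma amplitude are dropped (strict percentile band), as are elements
    from cycles with running speed above ``speed_cut`` cm/s.
    """
    cols = FEATURES + ["channel", "layer", "trial", "cycle_id", "section",
                       "section_alt", "speed"]
    if not elements:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame([vars(e) for e in elements])[cols]

    def trim(g: pd.DataFrame) -> pd.DataFrame:
        lo = np.percentile(g["gamma_amplitude"], trim_pct)
        hi = np.percentile(g["gamma_amplitude"], 100.0 - trim_pct)
        return g[(g["gamma_amplitude"] > lo) & (g["gamma_amplitude"] < hi)]

    df = pd.concat([trim(g) for _, g in df.groupby(["trial", "channel"])],
                   ignore_index=True)
    df = df[~(df["speed"] > speed_cut)].reset_index(drop=True)
    return df


def gamma_band_ratio(pdf: np.ndarray, freq_grid: np.ndarray) -> float:
    """Balance between the medium- and slow-gamma modes of a frequency pdf.

    ``gamma_S`` (``gamma_M``) is the probability mass in the contiguous region
    around the pdf mode inside 25-50 Hz (60-100 Hz) where the density stays at
    or above half the mode's density.  Returns
    ``(gamma_M - gamma_S) / (gamma_M + gamma_S)`` in [-1, 1].
    """
    pdf = np.asarray(pdf, dtype=float)
    freq_grid = np.asarray(freq_grid, dtype=float)

    def mode_mass(lo: float, hi: float) -> float:
        band = np.nonzero((freq_grid >= lo) & (freq_grid <= hi))[0]
        if len(band) == 0 or pdf[band].max() <= 0:
            return 0.0
        # a genuine mode is a local maximum of the pdf inside the band,
        # not the rising edge of a peak that lives in the other band
        local = [i for i in band
                 if (i == 0 or pdf[i] >= pdf[i - 1])
                 and (i == len(pdf) - 1 or pdf[i] >= pdf[i + 1])]
        if not local:
            return 0.0
        peak = max(local, key=lambda i: pdf[i])
        half = 0.5 * pdf[peak]
        left_edge = peak
        while left_edge > 0 and pdf[left_edge - 1] >= half:
            left_edge -= 1
        right_edge = peak
        while right_edge < len(pdf) - 1 and pdf[right_edge + 1] >= half:
            right_edge += 1
        return float(pdf[left_edge:right_edge + 1].sum())

    gamma_s = mode_mass(25.0, 50.0)
    gamma_m = mode_mass(60.0, 100.0)
    if gamma_s == 0.0 and gamma_m == 0.0:
        raise ValueError("no gamma mode found in either band")
    return (gamma_m - gamma_s) / (gamma_m + gamma_s)


def compare_distributions_kl(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    reps: int = 2000,
    subsample: int = 1500,
    n_bins: int = 30,
    seed: int | None = None,
) -> dict:
    """Bootstrap Kullback-Leibler comparison of two feature samples.

    Repeatedly subsamples both groups, histograms them on a common grid
    (additive smoothing for empty bins) and averages KL(A||B).  The null is
    built the same way from label-shuffled pools; the difference is judged
    significant when the observed mean divergence exceeds the upper 95% bound
    of the null divergence distribution (the calibrated permutation form).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < subsample or len(b) < subsample:
        raise ValueError("samples must be at least `subsample` long")
    rng = np.random.default_rng(seed)
    edges = np.histogram_bin_edges(np.concatenate([a, b]), bins=n_bins)

    def kl(x: np.ndarray, y: np.ndarray) -> float:
        # half-count additive smoothing keeps empty bins from dominating
        p = np.histogram(x, bins=edges)[0] + 0.5
        q = np.histogram(y, bins=edges)[0] + 0.5
        p, q = p / p.sum(), q / q.sum()
        return float(np.sum(p * np.log2(p / q)))

    obs = np.empty(reps)
    null = np.empty(reps)
    pool = np.concatenate([a, b])
    for r in range(reps):
        obs[r] = kl(rng.choice(a, subsample, replace=False),
                    rng.choice(b, subsample, replace=False))
        perm = rng.permutation(pool)
        null[r] = kl(rng.choice(perm[:len(a)], subsample, replace=False),
                     rng.choice(perm[len(a):], subsample, replace=False))
    null_upper = float(np.percentile(null, 95.0))
    return {
        "divergence": float(obs.mean()),
        "null_mean": float(null.mean()),
        "null_upper_95": null_upper,
        "significant": bool(obs.mean() > null_upper),
    }
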