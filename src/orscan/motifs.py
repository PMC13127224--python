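"""De novo conserved-motif discovery on OR peptides (ZOOPS EM).

The model is the classic zero-or-one-occurrence-per-sequence mixture: a
sequence either contains one motif occurrence (probability gamma, site
position uniform over valid offsets) or is pure background. The motif is
a position weight matrix over the 20 amino acids; the background is the
0-order empirical residue distribution of the input set. EM alternates
site-posterior computation with pseudocount-regularized PWM and gamma
updates, and is deterministic given its seed.

Top-k discovery runs EM over a width grid (widths 5-50) with multiple
seeded restarts, keeps the best motif by a length-penalized
log-likelihood ratio, masks its sites, and repeats. Masked positions are
neutral: windows overlapping them are excluded as candidate sites, so
successive motifs never overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_A = len(ALPHABET)
_AA_IDX = {a: i for i, a in enumerate(ALPHABET)}

WIDTH_RANGE = (5, 50)
DEFAULT_WIDTH_GRID = (8, 10, 12, 15, 20, 30, 50)
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_RESTARTS = 5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100


@dataclass
class MotifModel:
    width: int
    pwm: np.ndarray  # (20, width), columns sum to 1
    background: np.ndarray  # (20,)
    sites: list  # (seq_id, offset)
    log_likelihood_ratio: float
    consensus: str
    ic_profile: np.ndarray  # bits per column
    gamma: float = 0.0
    ll_trace: list = field(default_factory=list)
    score: float = 0.0  # length-penalized LLR used for ranking


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_IDX.get(c, -1) for c in seq), dtype=np.int64, count=len(seq))


class _MotifData:
    """Encoded sequences with a mutable neutral-position mask."""

    def __init__(self, sequences: list[str], ids: list[str] | None = None):
        if len(sequences) < 2:
            raise ValueError("need at least 2 sequences")
        self.ids = ids if ids is not None else [f"seq{i}" for i in range(len(sequences))]
        self.encoded = [_encode(s) for s in sequences]
        self.masked = [np.zeros(len(s), dtype=bool) for s in sequences]
        counts = np.zeros(_A)
        for e in self.encoded:
            counts += np.bincount(e[e >= 0], minlength=_A)
        total = counts.sum()
        if total == 0:
            raise ValueError("no standard residues in input")
        self.background = (counts + 1.0) / (total + _A)

    def neutralized(self, idx: int) -> np.ndarray:
        """Sequence codes with masked positions set to -1 (neutral)."""
        s = self.encoded[idx].copy()
        s[self.masked[idx]] = -1
        return s

    def mask_site(self, idx: int, offset: int, width: int) -> None:
        self.masked[idx][offset : offset + width] = True


def _valid_offsets(s: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Window view and boolean validity (no neutral residue in window)."""
    if len(s) < width:
        return np.empty((0, width), dtype=np.int64), np.empty(0, dtype=bool)
    windows = sliding_window_view(s, width)
    return windows, ~(windows < 0).any(axis=1)


def _ic_profile(pwm: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(pwm > 0, pwm * np.log2(pwm), 0.0).sum(axis=0)
    return np.clip(np.log2(_A) + h, 0.0, np.log2(_A))


def _run_em(
    data: _MotifData,
    width: int,
    init_pwm: np.ndarray,
    max_iter: int,
    tol: float,
    pseudocount: float,
    shift_refine: bool = True,
) -> MotifModel:
    seqs = [data.neutralized(i) for i in range(len(data.encoded))]
    prepared = []
    for i, s in enumerate(seqs):
        windows, valid = _valid_offsets(s, width)
        m = int(valid.sum())
        if m > 0:
            prepared.append((i, windows, valid, m))
    if not prepared:
        raise ValueError("no sequence offers a valid window at this width")

    log_bg = np.log(data.background)
    col_idx = np.arange(width)

    def em_from(start_pwm: np.ndarray):
        pwm = start_pwm.copy()
        gamma = 0.5
        trace: list[float] = []
        prev_ll = -np.inf
        for _ in range(max_iter):
            w_log = np.log(pwm) - log_bg[:, None]
            z_list = []
            q_list = []
            ll = 0.0
            for i, windows, valid, m in prepared:
                llr = w_log[windows[valid], col_idx].sum(axis=1)
                log_site = np.log(gamma / m) + llr
                log_denom = np.logaddexp(np.log1p(-gamma), logsumexp(log_site))
                z = np.exp(log_site - log_denom)
                z_list.append((i, windows, valid, z))
                q_list.append(z.sum())
                ll += log_denom

            # objective at the parameters the E-step just used
            penalized = ll + pseudocount * np.log(pwm).sum()
            trace.append(penalized)

            counts = np.full((_A, width), pseudocount)
            for i, windows, valid, z in z_list:
                vw = windows[valid]
                for k in range(width):
                    counts[:, k] += np.bincount(vw[:, k], weights=z, minlength=_A)
            pwm = counts / counts.sum(axis=0, keepdims=True)
            gamma = float(np.clip(np.mean(q_list), 1e-4, 1 - 1e-4))

            if penalized - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = penalized
        return pwm, gamma, trace

    pwm, gamma, ll_trace = em_from(init_pwm)

    if shift_refine:
        # column-shift moves: EM converges readily to off-by-one optima,
        # so retry from the converged PWM slid left/right (vacated columns
        # filled with background) and keep any improvement
        for _ in range(4):
            improved = False
            for delta in (-2, -1, 1, 2):
                shifted = np.tile(data.background[:, None], (1, width))
                if delta > 0:
                    shifted[:, : width - delta] = pwm[:, delta:]
                else:
                    shifted[:, -delta:] = pwm[:, :delta]
                cand_pwm, cand_gamma, cand_trace = em_from(shifted)
                if cand_trace[-1] > ll_trace[-1] + 1e-9:
                    pwm, gamma, ll_trace = cand_pwm, cand_gamma, cand_trace
                    improved = True
                    break
            if not improved:
                break

    # final E-step for sites and the reported LLR
    w_log = np.log(pwm) - log_bg[:, None]
    sites = []
    llr_total = 0.0
    for i, windows, valid, m in prepared:
        llr = w_log[windows[valid], col_idx].sum(axis=1)
        log_site = np.log(gamma / m) + llr
        log_denom = np.logaddexp(np.log1p(-gamma), logsumexp(log_site))
        z = np.exp(log_site - log_denom)
        llr_total += log_denom
        j = int(np.argmax(z))
        if z[j] >= 0.5:
            offset = int(np.nonzero(valid)[0][j])
            sites.append((data.ids[i], offset))

    consensus = "".join(ALPHABET[a] for a in pwm.argmax(axis=0))
    return MotifModel(
        width=width,
        pwm=pwm,
        background=data.background.copy(),
        sites=sites,
        log_likelihood_ratio=float(llr_total),
        consensus=consensus,
        ic_profile=_ic_profile(pwm),
        gamma=gamma,
        ll_trace=ll_trace,
    )


def _init_from_window(window: np.ndarray, weight: float = 0.5) -> np.ndarray:
    width = len(window)
    pwm = np.full((_A, width), (1 - weight) / (_A - 1))
    pwm[window, np.arange(width)] = weight
    return pwm


def _sample_starts(data: _MotifData, width: int, rng: np.random.Generator, n: int):
    """Sample candidate starting windows uniformly over valid offsets."""
    pool = []
    for i in range(len(data.encoded)):
        s = data.neutralized(i)
        _, valid = _valid_offsets(s, width)
        for off in np.nonzero(valid)[0]:
            pool.append((i, int(off)))
    if not pool:
        return []
    picks = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    return [pool[p] for p in picks]


def em_zoops(
    sequences: list[str],
    width: int,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ids: list[str] | None = None,
) -> MotifModel:
    """Fit one ZOOPS motif of the given width.

    The starting PWM is seeded from a randomly chosen input window
    (deterministic for a fixed seed). Sequences shorter than the width
    are skipped with a warning.
    """
    if not (WIDTH_RANGE[0] <= width <= WIDTH_RANGE[1]):
        raise ValueError(f"width {width} outside {WIDTH_RANGE}")
    short = [i for i, s in enumerate(sequences) if len(s) < width]
    if short:
        warnings.warn(f"skipping {len(short)} sequence(s) shorter than width {width}")
    data = _MotifData(sequences, ids)
    rng = np.random.default_rng(seed)
    starts = _sample_starts(data, width, rng, 1)
    if not starts:
        raise ValueError("no sequence long enough for this width")
    i, off = starts[0]
    init = _init_from_window(data.neutralized(i)[off : off + width])
    return _run_em(data, width, init, max_iter, tol, pseudocount)


def _penalized_score(model: MotifModel) -> float:
    """BIC-style length penalty: (A-1)/2 free parameters per column,
    scaled by log of the realized site count."""
    n_sites = max(2, len(model.sites))
    return model.log_likelihood_ratio - 0.5 * (_A - 1) * model.width * np.log(n_sites)


def discover_top_motifs(
    sequences: list[str],
    n_motifs: int = 5,
    width_grid: tuple[int, ...] | None = None,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    n_candidates: int = 10,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    scan_all_widths: bool = False,
    ids: list[str] | None = None,
) -> list[MotifModel]:
    """Iteratively discover up to ``n_motifs`` non-overlapping motifs.

    For each rank, EM runs over the width grid with seeded restarts; each
    restart screens several candidate starting windows with a short EM
    burn-in and refines the best. The winner (by length-penalized LLR) has
    its sites masked before the next rank. Returned motifs are ordered by
    decreasing log-likelihood ratio of discovery.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    grid = (
        tuple(range(WIDTH_RANGE[0], WIDTH_RANGE[1] + 1))
        if scan_all_widths
        else tuple(width_grid or DEFAULT_WIDTH_GRID)
    )
    for w in grid:
        if not (WIDTH_RANGE[0] <= w <= WIDTH_RANGE[1]):
            raise ValueError(f"width {w} outside {WIDTH_RANGE}")

    data = _MotifData(sequences, ids)
    id_to_idx = {sid: i for i, sid in enumerate(data.ids)}
    found: list[MotifModel] = []

    for rank in range(n_motifs):
        best: MotifModel | None = None
        for wi, width in enumerate(grid):
            if all(len(s) < width for s in sequences):
                continue
            for r in range(n_restarts):
                rng = np.random.default_rng([seed, rank, wi, r])
                starts = _sample_starts(data, width, rng, n_candidates)
                if not starts:
                    continue
                # short burn-in to rank the candidate starts
                trial_best, trial_init = -np.inf, None
                for i, off in starts:
                    init = _init_from_window(data.neutralized(i)[off : off + width])
                    probe = _run_em(data, width, init, 2, tol, pseudocount, shift_refine=False)
                    if probe.log_likelihood_ratio > trial_best:
                        trial_best = probe.log_likelihood_ratio
                        trial_init = init
                model = _run_em(data, width, trial_init, max_iter, tol, pseudocount)
                model.score = _penalized_score(model)
                if best is None or model.score > best.score:
                    best = model
        if best is None or not best.sites:
            break
        found.append(best)
        for sid, off in best.sites:
            data.mask_site(id_to_idx[sid], off, best.width)

    found.sort(key=lambda m: -m.log_likelihood_ratio)
    return found


def write_motifs(motifs: list[MotifModel], out_prefix: str) -> str:
    """Write a summary TSV plus one PWM/IC matrix file per motif."""
    summary = f"{out_prefix}.tsv"
    with open(summary, "w") as fh:
        fh.write("rank\twidth\tconsensus\tllr\tn_sites\tgamma\n")
        for rank, m in enumerate(motifs, start=1):
            fh.write(
                f"{rank}\t{m.width}\t{m.consensus}\t{m.log_likelihood_ratio:.4f}\t"
                f"{len(m.sites)}\t{m.gamma:.4f}\n"
            )
            with open(f"{out_prefix}.motif{rank}.pwm.tsv", "w") as pf:
                pf.write("residue\t" + "\t".join(str(k) for k in range(m.width)) + "\n")
                for a, row in zip(ALPHABET, m.pwm):
                    pf.write(a + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
                pf.write("IC\t" + "\t".join(f"{v:.4f}" for v in m.ic_profile) + "\n")
    return summary
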