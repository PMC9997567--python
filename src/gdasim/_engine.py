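"""Vectorized hybrid stochastic/deterministic advancement of clone batches.

Each clone is a row of a (clones x copy-number) count matrix.  Per sub-day
step, each class divides with probability ``2**(g(n)*dt) - 1`` (so that a
class growing at ``g`` divisions/day multiplies by ``2**(g*dt)`` per step);
a dividing cell undergoes an unequal sister-chromosome exchange with
probability ``min(1, k_rec*(n-1))``, sending daughters to ``n + d`` and
``n - d`` with ``d`` uniform on ``1..n-1``.

Classes below ``stochastic_threshold`` are advanced by exact integer
sampling (binomial divisions and exchanges, uniform offsets); larger
classes are advanced deterministically in expectation, with the exchange
mass spread uniformly over the offset range via a difference-array trick.
Fractional deterministic mass seeded into small classes is carried
deterministically; the early (fate-deciding) phase of every clone founded
by a single cell is therefore exactly stochastic.
"""

from __future__ import annotations

import math

import numpy as np

from .config import RateConfig
from .core import growth_rate

__all__ = ["CloneBatch"]

# above this many events in one (clone, class) cell per step, exchange and
# collapse offsets are spread deterministically instead of sampled per event
_EVENT_CAP = 64


class CloneBatch:
    """Advance many independent selective-plate clones in lockstep.

    Parameters
    ----------
    founder_copy_numbers
        Integer array, one founder cell per clone (all ``>= 2``; haploids
        cannot initiate selective clones).
    growing
        Optional boolean mask: clones whose amplicon is non-permissive
        neither grow nor exchange (they stay at their founder state).
    config, rng
        Model parameters and the random generator that receives every draw.
    """

    def __init__(
        self,
        founder_copy_numbers: np.ndarray,
        config: RateConfig,
        rng: np.random.Generator,
        growing: np.ndarray | None = None,
    ) -> None:
        founders = np.asarray(founder_copy_numbers, dtype=np.int64)
        if founders.size and founders.min() < 2:
            raise ValueError("founder copy numbers must be >= 2")
        self.config = config
        self.rng = rng
        nmax = config.max_copy_number
        founders = np.minimum(founders, nmax)
        m = founders.size
        self.m = m
        self.nmax = nmax
        self.counts = np.zeros((m, nmax + 1), dtype=np.float64)
        if m:
            self.counts[np.arange(m), founders] = 1.0
        self.growing = (
            np.ones(m, dtype=bool) if growing is None else np.asarray(growing, bool).copy()
        )
        self.appearance_day = np.full(m, np.nan)
        self.time = 0.0
        # incremental bookkeeping: per-clone totals and the highest occupied
        # copy-number column (keeps per-step scans narrow)
        self._totals = self.counts.sum(axis=1)
        self._max_col = int(founders.max()) if m else 2

        # per-copy-number rates (index = copy number)
        n = np.arange(nmax + 1, dtype=np.float64)
        g = np.array([0.0, 0.0] + [growth_rate(int(k), config) for k in range(2, nmax + 1)])
        g *= config.temp_factor
        dt = config.dt_days
        if g.max() * dt > 1.0 + 1e-9:
            # keep per-step division probability a probability
            raise ValueError("dt_days too large for g_max: require g_max*temp_factor*dt <= 1")
        self._p_div = 2.0 ** (g * dt) - 1.0
        self._q = np.minimum(1.0, config.k_rec * config.temp_factor * np.maximum(n - 1.0, 0.0))
        self._r_intra = np.minimum(
            1.0,
            config.intra_collapse_weight
            * config.k_rec
            * config.temp_factor
            * np.maximum(n - 1.0, 0.0),
        )
        self._dt = dt

    # -----------------------------------------------------------------

    def _step(self) -> None:
        cfg = self.config
        active = self.growing & np.isnan(self.appearance_day)
        if not active.any():
            self.time += self._dt
            return
        rows_active = np.nonzero(active)[0]
        C = self.counts
        hi_col = self._max_col
        sub = C[rows_active, 2 : hi_col + 1]  # only n >= 2 divides
        r_idx, c_idx = np.nonzero(sub)
        if r_idx.size == 0:
            self.time += self._dt
            return
        rows = rows_active[r_idx]
        cols = c_idx + 2
        c = C[rows, cols]
        p = self._p_div[cols]
        q = self._q[cols]

        c_int = np.floor(c)
        c_frac = c - c_int
        stoch = c < cfg.stochastic_threshold

        # divisions
        D_int = np.zeros_like(c)
        D_det = np.empty_like(c)
        if stoch.any():
            D_int[stoch] = self.rng.binomial(c_int[stoch].astype(np.int64), p[stoch])
        D_det = np.where(stoch, c_frac * p, c * p)

        # exchanging divisions
        E_int = np.zeros_like(c)
        if stoch.any():
            E_int[stoch] = self.rng.binomial(D_int[stoch].astype(np.int64), q[stoch])
        E_det = D_det * q
        # deterministic entries have no integer part
        det = ~stoch
        if det.any():
            E_int[det] = 0.0

        # intrachromosomal deletions among the same-class daughters
        # (2 per non-exchanging division, each collapsing with prob r)
        r_i = self._r_intra[cols]
        I_int = np.zeros_like(c)
        if stoch.any():
            n_same = 2.0 * (D_int[stoch] - E_int[stoch])
            I_int[stoch] = self.rng.binomial(n_same.astype(np.int64), r_i[stoch])
        I_det = 2.0 * (D_det - E_det) * r_i

        # +1 per normal division, -1 per exchange, minus intra collapses
        total_D = D_int + D_det
        total_E = E_int + E_det
        C[rows, cols] += total_D - 2.0 * total_E - (I_int + I_det)

        # event-count redistribution: per-event sampling is exact for small
        # counts; entries with many events are spread deterministically
        # (the uniform-offset law averages out)
        big = E_int > _EVENT_CAP
        if big.any():
            E_det = E_det + np.where(big, E_int, 0.0)
            E_int = np.where(big, 0.0, E_int)
        big_i = I_int > _EVENT_CAP
        if big_i.any():
            I_det = I_det + np.where(big_i, I_int, 0.0)
            I_int = np.where(big_i, 0.0, I_int)

        # redistribute stochastic exchanges exactly
        ex = E_int > 0
        if ex.any():
            ex_rows = np.repeat(rows[ex], E_int[ex].astype(np.int64))
            ex_n = np.repeat(cols[ex], E_int[ex].astype(np.int64))
            d = (self.rng.random(ex_n.size) * (ex_n - 1)).astype(np.int64) + 1
            up = np.minimum(ex_n + d, self.nmax)
            down = ex_n - d
            np.add.at(C, (ex_rows, up), 1.0)
            np.add.at(C, (ex_rows, down), 1.0)
            self._max_col = max(self._max_col, int(up.max()))

        # redistribute stochastic intra collapses (n -> n - d)
        ic = I_int > 0
        if ic.any():
            ic_rows = np.repeat(rows[ic], I_int[ic].astype(np.int64))
            ic_n = np.repeat(cols[ic], I_int[ic].astype(np.int64))
            d = (self.rng.random(ic_n.size) * (ic_n - 1)).astype(np.int64) + 1
            np.add.at(C, (ic_rows, ic_n - d), 1.0)

        # redistribute deterministic exchange mass uniformly over offsets
        dm = E_det > 0
        if dm.any():
            for n_col in np.unique(cols[dm]):
                sel = dm & (cols == n_col)
                r = rows[sel]
                v = E_det[sel] / (n_col - 1)  # mass per offset, per daughter
                hi = min(2 * n_col - 1, self.nmax)
                C[r, 1 : hi + 1] += v[:, None]
                C[r, n_col] -= v
                overflow = (2 * n_col - 1) - self.nmax
                if overflow > 0:
                    C[r, self.nmax] += v * overflow
                self._max_col = max(self._max_col, hi)

        # deterministic intra-collapse mass spread over lower classes
        im = I_det > 0
        if im.any():
            for n_col in np.unique(cols[im]):
                sel = im & (cols == n_col)
                r = rows[sel]
                v = I_det[sel] / (n_col - 1)
                C[r, 1:n_col] += v[:, None]

        # every division adds one net cell; exchanges and collapses conserve
        self._totals += np.bincount(rows, weights=total_D, minlength=self.m)

        self.time += self._dt
        crossed = self._totals[rows_active] >= cfg.n_vis
        if crossed.any():
            day = math.ceil(self.time - 1e-9)
            self.appearance_day[rows_active[crossed]] = max(1, day)

    # -----------------------------------------------------------------

    def run(self, days: float) -> np.ndarray:
        """Advance until ``self.time >= days``; returns appearance days
        (NaN for clones that never reached visibility)."""
        n_steps = int(round((days - self.time) / self._dt))
        for _ in range(n_steps):
            self._step()
        return self.appearance_day

    def visible_by_day(self, days: int) -> np.ndarray:
        """Cumulative number of visible clones for days 1..days."""
        out = np.zeros(days, dtype=np.int64)
        appeared = self.appearance_day[~np.isnan(self.appearance_day)]
        for day in range(1, days + 1):
            out[day - 1] = int((appeared <= day).sum())
        return out

    def modal_copy_numbers(self) -> np.ndarray:
        """Modal copy number (n >= 1) per clone at its current state."""
        return np.argmax(self.counts[:, 1:], axis=1) + 1
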