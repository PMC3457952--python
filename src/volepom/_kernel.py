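"""Compiled daily scheduler for the vole world.

State is struct-of-arrays; one call to :func:`run_days` advances the world a
span of days.  The decision rules here mirror the documented per-operation
API in :mod:`volepom.abm`; that module is the readable reference for the
behavioural logic.

Per-day order of execution: vegetation update -> per-vole (freshly shuffled
order): mortality, aging/maturation, territory assessment and eviction,
mating/reproduction, restlessness, dispersal -> weaning -> predator step ->
trap census and recording.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# parameter-vector indices (float64 array P)
P_MALE_MIN_AGE = 0
P_FEMALE_MIN_AGE = 1
P_QUALITY_MULT = 2
P_F_MIN_R = 3
P_F_MAX_R = 4
P_M_MIN_R = 5
P_M_MAX_R = 6
P_EVICT_GAP = 7
P_DISP_MORT = 8
P_DAILY_MORT = 9
P_MALE_MOVE = 10
P_DENS_THRESH = 11
P_V17 = 12
P_WEAN_AGE = 13
P_LIFE_MEAN_D = 14
P_LIFE_SD_D = 15
P_GESTATION = 16
P_LITTER_MEAN = 17
P_DISP_STEP = 18
P_INF_RADIUS = 19
P_MALE_NEEDS_F = 20
P_BIOMASS_DECAY = 21
P_MALE_EXC_PROB = 22
P_MALE_EXC_RADIUS = 23
P_P_FAR = 24
P_DISP_MIN_D = 25
P_DISP_MAX_D = 26
P_MALE_RANGE_R = 27
P_DISP_MALE_X = 28
P_OBLIGATE_STEP = 29
P_THRESH_MODE = 30
P_EXC_OFFSEASON = 31
P_DD_GATE = 32
NP_PARAMS = 33

# predator-parameter indices (float64 array PP)
Q_HOME_R = 0
Q_KILL_CAP = 1
Q_SURVIVE_THRESH = 2
Q_REPRO_THRESH = 3
Q_UNSUCC_DISP = 4
Q_STARVE_DAYS = 5
Q_DISP_STEP = 6
Q_REPRO_START = 7
Q_REPRO_END = 8
Q_MAX_PREDS = 9
Q_IMMIGRATION = 10
Q_LITTER = 11
NQ_PARAMS = 12

# death-cause counters
D_LIFESPAN = 0
D_BACKGROUND = 1
D_DISPERSAL = 2
D_PREDATION = 3
D_INFANTICIDE = 4
ND_CAUSES = 5

RING_MAX = 64
NEW_GREEN_AGE = 14
HASH_BS = 32


def build_rings(rmax: int = RING_MAX):
    """Concatenated ring offsets: ring r = cells with r-1 < dist <= r."""
    dys, dxs = [], []
    ptr = [0]
    span = np.arange(-rmax, rmax + 1)
    yy, xx = np.meshgrid(span, span, indexing="ij")
    dist = np.hypot(yy, xx)
    for r in range(rmax + 1):
        lo = r - 1 if r > 0 else -1.0
        sel = (dist > lo) & (dist <= r)
        dys.append(yy[sel])
        dxs.append(xx[sel])
        ptr.append(ptr[-1] + sel.sum())
    return (np.concatenate(dys).astype(np.int32),
            np.concatenate(dxs).astype(np.int32),
            np.array(ptr, dtype=np.int64))


RING_DY, RING_DX, RING_PTR = build_rings()


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _overlap_fraction(r_self, r_other, d):
    """Area of the circle-circle lens divided by the self circle's area."""
    if d >= r_self + r_other:
        return 0.0
    rmin = min(r_self, r_other)
    if d <= abs(r_self - r_other):
        lens = np.pi * rmin * rmin
    else:
        d2 = d * d
        a2 = r_self * r_self
        b2 = r_other * r_other
        alpha = np.arccos((d2 + a2 - b2) / (2.0 * d * r_self))
        beta = np.arccos((d2 + b2 - a2) / (2.0 * d * r_other))
        lens = (a2 * (alpha - np.sin(2 * alpha) / 2.0)
                + b2 * (beta - np.sin(2 * beta) / 2.0))
    return lens / (np.pi * r_self * r_self)


@njit(cache=True)
def _settle_scan(cx, cy, sex, window_open, self_here,
                 baseq, digest, qmul, patch, occ, occ_af,
                 ring_dy, ring_dx, ring_ptr, P):
    """Smallest acceptable territory radius at (cx, cy), or 0.

    Acceptable: mean cell quality * V3 >= 1, local occupant count below the
    sex-scaled density threshold, and (for adult males in the breeding
    window, when enabled) at least one adult female within the radius.
    """
    H, W = occ.shape
    if sex == 0:
        rmin = int(P[P_F_MIN_R])
        rmax = int(P[P_F_MAX_R])
        thr = P[P_DENS_THRESH]
    else:
        rmin = int(P[P_M_MIN_R])
        rmax = int(P[P_M_MAX_R])
        rr = P[P_M_MIN_R] / P[P_F_MIN_R]
        thr = P[P_DENS_THRESH] * rr * rr
        if P[P_THRESH_MODE] == 0.0 or P[P_THRESH_MODE] == 2.0:
            thr = np.floor(thr)
    need_female = sex == 1 and window_open and P[P_MALE_NEEDS_F] > 0.5
    qsum = 0.0
    ncell = 0
    osum = 0
    afsum = 0
    # quality is judged on the core range (the sex minimum radius); larger
    # radii only relax the search for mates, not the forage criterion
    for r in range(rmax + 1):
        for k in range(ring_ptr[r], ring_ptr[r + 1]):
            y = cy + ring_dy[k]
            x = cx + ring_dx[k]
            if y < 0 or y >= H or x < 0 or x >= W:
                continue
            ncell += 1
            pid = patch[y, x]
            qsum += baseq[pid] * digest[pid] * qmul[y, x]
            osum += occ[y, x]
            afsum += occ_af[y, x]
        if r < rmin or ncell == 0:
            continue
        if r == rmin and (qsum / ncell) * P[P_QUALITY_MULT] < 1.0:
            return 0
        others = osum - 1 if self_here else osum
        if others < thr:
            if need_female and afsum < 1:
                continue
            return r
    return 0


@njit(cache=True)
def _disk_stats(cx, cy, r, baseq, digest, qmul, patch, occ, occ_af,
                ring_dy, ring_dx, ring_ptr):
    """Mean quality, occupant count and adult-female count within radius r."""
    H, W = occ_af.shape
    qsum = 0.0
    ncell = 0
    osum = 0
    afsum = 0
    for rr in range(r + 1):
        for k in range(ring_ptr[rr], ring_ptr[rr + 1]):
            y = cy + ring_dy[k]
            x = cx + ring_dx[k]
            if y < 0 or y >= H or x < 0 or x >= W:
                continue
            ncell += 1
            pid = patch[y, x]
            qsum += baseq[pid] * digest[pid] * qmul[y, x]
            osum += occ[y, x]
            afsum += occ_af[y, x]
    if ncell == 0:
        return 0.0, 0, 0
    return qsum / ncell, osum, afsum


@njit(cache=True)
def _count_occ_disk(cx, cy, r, occ, ring_dy, ring_dx, ring_ptr):
    H, W = occ.shape
    s = 0
    for rr in range(r + 1):
        for k in range(ring_ptr[rr], ring_ptr[rr + 1]):
            y = cy + ring_dy[k]
            x = cx + ring_dx[k]
            if 0 <= y < H and 0 <= x < W:
                s += occ[y, x]
    return s


@njit(cache=True)
def _hash_insert(heads, nxt, bx_n, x, y, idx):
    b = (y // HASH_BS) * bx_n + (x // HASH_BS)
    nxt[idx] = heads[b]
    heads[b] = idx


@njit(cache=True)
def _find_free(alive, start):
    n = alive.shape[0]
    for k in range(n):
        i = (start + k) % n
        if alive[i] == 0:
            return i
    return -1


@njit(cache=True)
def _vegetation_day(veg_ring, veg_total, veg_head_arr, digest,
                    growth_p, grow_today, decay):
    head = (veg_head_arr[0] - 1) % NEW_GREEN_AGE
    veg_head_arr[0] = head
    npatch = veg_total.shape[0]
    for p in range(npatch):
        veg_total[p] *= (1.0 - decay)
        for k in range(NEW_GREEN_AGE):
            veg_ring[p, k] *= (1.0 - decay)
        inc = growth_p[p] if grow_today else 0.0
        veg_ring[p, head] = inc
        veg_total[p] += inc
        if veg_total[p] > 0.0:
            newg = 0.0
            for k in range(NEW_GREEN_AGE):
                newg += veg_ring[p, k]
            f = newg / veg_total[p]
            if f > 1.0:
                f = 1.0
            q = 0.7 + np.sqrt(f)
            digest[p] = q if q < 1.0 else 1.0
        else:
            digest[p] = 0.7


@njit(cache=True)
def _kill_agent(v, cause, alive, sex, age, x, y, nursing, l_alive,
                occ, occ_af, deaths, female_min_age):
    alive[v] = 0
    occ[y[v], x[v]] -= 1
    if sex[v] == 0 and age[v] >= female_min_age:
        occ_af[y[v], x[v]] -= 1
    if nursing[v] >= 0:
        l_alive[nursing[v]] = 0
        nursing[v] = -1
    deaths[cause * 2 + sex[v]] += 1


@njit(cache=True)
def _check_eviction(v, th_heads, th_next, bx_n, by_n,
                    alive, sex, age, tx, ty, tr, P):
    """True if a sufficiently older same-sex territory overlaps v's by >50%."""
    bx0 = tx[v] // HASH_BS
    by0 = ty[v] // HASH_BS
    min_gap = P[P_EVICT_GAP]
    for by in range(max(0, by0 - 2), min(by_n, by0 + 3)):
        for bx in range(max(0, bx0 - 2), min(bx_n, bx0 + 3)):
            u = th_heads[by * bx_n + bx]
            while u >= 0:
                if (u != v and alive[u] == 1 and tr[u] > 0
                        and sex[u] == sex[v]
                        and age[u] - age[v] >= min_gap):
                    d = np.hypot(float(tx[u] - tx[v]), float(ty[u] - ty[v]))
                    if _overlap_fraction(float(tr[v]), float(tr[u]), d) > 0.5:
                        return True
                u = th_next[u]
    return False


@njit(cache=True)
def _find_mate(v, th_heads, th_next, bx_n, by_n,
               alive, sex, age, x, y, tx, ty, tr, uid, P):
    """Nearest adult male whose territory contains the female's position."""
    best_d = 1.0e18
    best_uid = np.int64(2 ** 62)
    best = -1
    bx0 = x[v] // HASH_BS
    by0 = y[v] // HASH_BS
    for by in range(max(0, by0 - 2), min(by_n, by0 + 3)):
        for bx in range(max(0, bx0 - 2), min(bx_n, bx0 + 3)):
            u = th_heads[by * bx_n + bx]
            while u >= 0:
                if (alive[u] == 1 and sex[u] == 1 and tr[u] > 0
                        and age[u] >= P[P_MALE_MIN_AGE]):
                    d = np.hypot(float(tx[u] - x[v]), float(ty[u] - y[v]))
                    if d <= tr[u] and (d < best_d or
                                       (d == best_d and uid[u] < best_uid)):
                        best_d = d
                        best_uid = uid[u]
                        best = u
                u = th_next[u]
    return best


@njit(cache=True)
def _infanticide_scan(ex, ey, t, alive, nursing, l_alive, l_mother,
                      l_x, l_y, l_born, l_size, live_l, n_live_l,
                      deaths, P):
    """A roaming adult male attacks unweaned litters near (ex, ey)."""
    irad = P[P_INF_RADIUS]
    for lk in range(n_live_l):
        li = live_l[lk]
        if l_alive[li] == 1:
            d = np.hypot(float(l_x[li] - ex), float(l_y[li] - ey))
            if d <= irad and np.random.random() < P[P_V17]:
                a = t - l_born[li]
                psucc = 1.0 - a / P[P_WEAN_AGE]
                if psucc > 0.0 and np.random.random() < psucc:
                    l_alive[li] = 0
                    m = l_mother[li]
                    if alive[m] == 1 and nursing[m] == li:
                        nursing[m] = -1
                    deaths[D_INFANTICIDE * 2] += l_size[li]


@njit(cache=True)
def _disperse_move(v, alive, sex, age, x, y, nursing, l_alive,
                   l_mother, l_x, l_y, l_born, l_size, live_l, n_live_l,
                   occ, occ_af, barrier, baseq, patch, heading, deaths, t,
                   adult, obligate, P):
    """One dispersal day: directed move, infanticide encounters, V9 hazard.

    Movement is a correlated walk along the vole's current heading; the
    heading is redrawn when the way is blocked.  Returns True if the vole
    died.
    """
    H, W = occ.shape
    if obligate:
        step_max = P[P_OBLIGATE_STEP]
        sigma = 0.15
    else:
        step_max = P[P_DISP_STEP]
        sigma = 0.7
    nx = x[v]
    ny = y[v]
    for _try in range(8):
        ang = heading[v] + np.random.normal(0.0, sigma)
        dist = (0.5 + 0.5 * np.random.random()) * step_max
        cx = int(round(x[v] + dist * np.cos(ang)))
        cy = int(round(y[v] + dist * np.sin(ang)))
        if 0 <= cx < W and 0 <= cy < H and barrier[cy, cx] == 0:
            # habitat-following: leaving forage-bearing habitat is mostly
            # refused, but occasional transits through hostile matrix remain
            if baseq[patch[cy, cx]] < 0.45 and np.random.random() > 0.25:
                heading[v] = np.random.random() * 2.0 * np.pi
                continue
            nx = cx
            ny = cy
            heading[v] = ang
            break
        heading[v] = np.random.random() * 2.0 * np.pi
    if nx != x[v] or ny != y[v]:
        occ[y[v], x[v]] -= 1
        occ[ny, nx] += 1
        if sex[v] == 0 and adult:
            occ_af[y[v], x[v]] -= 1
            occ_af[ny, nx] += 1
        x[v] = nx
        y[v] = ny
    if sex[v] == 1 and adult and P[P_V17] > 0.0:
        _infanticide_scan(x[v], y[v], t, alive, nursing, l_alive, l_mother,
                          l_x, l_y, l_born, l_size, live_l, n_live_l,
                          deaths, P)
    if np.random.random() < P[P_DISP_MORT]:
        _kill_agent(v, D_DISPERSAL, alive, sex, age, x, y, nursing,
                    l_alive, occ, occ_af, deaths, int(P[P_FEMALE_MIN_AGE]))
        return True
    return False


@njit(cache=True)
def _vole_loop(t, window, grow, baseq_p, digest, qmul, patch, barrier,
               alive, sex, age, x, y, natal_x, natal_y, lifespan,
               tx, ty, tr, uid, preg_due, nursing, heading, disp_left,
               l_alive, l_mother, l_x, l_y, l_born, l_size,
               live_l, n_live_l_arr,
               occ, occ_af, th_heads, th_next, th_in, order, deaths, overflow,
               free_l_arr, P, ring_dy, ring_dx, ring_ptr, bx_n, by_n):
    N = alive.shape[0]
    fem_min = int(P[P_FEMALE_MIN_AGE])
    gest = int(P[P_GESTATION])

    # shuffled processing order over currently-alive agents
    n_alive = 0
    for i in range(N):
        if alive[i] == 1:
            order[n_alive] = i
            n_alive += 1
    for i in range(n_alive - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp

    for oi in range(n_alive):
        v = order[oi]
        if alive[v] == 0:
            continue

        # mortality, then aging
        age[v] += 1
        if age[v] > lifespan[v]:
            _kill_agent(v, D_LIFESPAN, alive, sex, age, x, y, nursing,
                        l_alive, occ, occ_af, deaths, fem_min)
            continue
        if np.random.random() < P[P_DAILY_MORT]:
            _kill_agent(v, D_BACKGROUND, alive, sex, age, x, y, nursing,
                        l_alive, occ, occ_af, deaths, fem_min)
            continue

        # maturation: adult females enter the adult-female occupancy layer
        if sex[v] == 0 and age[v] == fem_min:
            occ_af[y[v], x[v]] += 1
        adult = (age[v] >= fem_min if sex[v] == 0
                 else age[v] >= int(P[P_MALE_MIN_AGE]))

        af_in_terr = 0
        if tr[v] > 0:
            rmin_s = int(P[P_F_MIN_R]) if sex[v] == 0 else int(P[P_M_MIN_R])
            meanq, occ_in_terr, af_in_terr = _disk_stats(
                tx[v], ty[v], tr[v], baseq_p, digest, qmul, patch, occ,
                occ_af, ring_dy, ring_dx, ring_ptr)
            if tr[v] > rmin_s:
                meanq, _oc, _af = _disk_stats(
                    tx[v], ty[v], rmin_s, baseq_p, digest, qmul, patch, occ,
                    occ_af, ring_dy, ring_dx, ring_ptr)
            if sex[v] == 0:
                thr = P[P_DENS_THRESH]
            else:
                rr_scale = P[P_M_MIN_R] / P[P_F_MIN_R]
                thr = P[P_DENS_THRESH] * rr_scale * rr_scale
                if P[P_THRESH_MODE] == 2.0 or P[P_THRESH_MODE] == 3.0:
                    thr = np.floor(thr)
            if meanq * P[P_QUALITY_MULT] < 1.0 or occ_in_terr - 1 >= thr:
                tr[v] = 0
            elif _check_eviction(v, th_heads, th_next, bx_n, by_n,
                                 alive, sex, age, tx, ty, tr, P):
                tr[v] = 0
            if tr[v] == 0:
                heading[v] = np.random.random() * 2.0 * np.pi
                disp_left[v] = 0

        # mating / conception (not while pregnant or nursing)
        if (tr[v] > 0 and sex[v] == 0 and adult and window
                and preg_due[v] < 0 and nursing[v] < 0):
            mate = _find_mate(v, th_heads, th_next, bx_n, by_n,
                              alive, sex, age, x, y, tx, ty, tr, uid, P)
            if mate >= 0:
                preg_due[v] = t + gest

        # male restlessness: no overlapping females -> abandon w.p. V12
        if (tr[v] > 0 and sex[v] == 1 and adult and window
                and af_in_terr == 0
                and np.random.random() < P[P_MALE_MOVE]):
            tr[v] = 0
            heading[v] = np.random.random() * 2.0 * np.pi
            disp_left[v] = 0

        # growing-season male excursion beyond the territory: infanticide
        # opportunity at the visited point, dispersal hazard (V9) applies
        exc_p = P[P_MALE_EXC_PROB] if window else (
            P[P_MALE_EXC_PROB] * P[P_EXC_OFFSEASON] if grow else 0.0)
        if (tr[v] > 0 and sex[v] == 1 and adult
                and np.random.random() < exc_p):
            H, W = occ.shape
            ang = np.random.random() * 2.0 * np.pi
            dist = (0.5 + 0.5 * np.random.random()) * P[P_MALE_EXC_RADIUS]
            ex = int(round(x[v] + dist * np.cos(ang)))
            ey = int(round(y[v] + dist * np.sin(ang)))
            if 0 <= ex < W and 0 <= ey < H and barrier[ey, ex] == 0:
                if P[P_V17] > 0.0:
                    _infanticide_scan(ex, ey, t, alive, nursing, l_alive,
                                      l_mother, l_x, l_y, l_born, l_size,
                                      live_l, int(n_live_l_arr[0]),
                                      deaths, P)
                if np.random.random() < P[P_DISP_MORT]:
                    _kill_agent(v, D_DISPERSAL, alive, sex, age, x, y,
                                nursing, l_alive, occ, occ_af, deaths,
                                fem_min)
                    continue

        # birth
        if sex[v] == 0 and preg_due[v] == t:
            preg_due[v] = -1
            if nursing[v] < 0:
                li = _find_free(l_alive, free_l_arr[0])
                if li >= 0:
                    free_l_arr[0] = li + 1
                    size = np.random.poisson(P[P_LITTER_MEAN])
                    if size < 1:
                        size = 1
                    l_alive[li] = 1
                    l_mother[li] = v
                    l_x[li] = tx[v] if tr[v] > 0 else x[v]
                    l_y[li] = ty[v] if tr[v] > 0 else y[v]
                    l_born[li] = t
                    l_size[li] = size
                    nursing[v] = li
                    if n_live_l_arr[0] < live_l.shape[0]:
                        live_l[n_live_l_arr[0]] = li
                        n_live_l_arr[0] += 1
                else:
                    overflow[0] += 1

        # dispersal: settle here if possible, otherwise move under hazard;
        # an obligate dispersal phase (innate disperser phenotype) postpones
        # settlement attempts
        if tr[v] == 0:
            r = 0
            if disp_left[v] > 0:
                disp_left[v] -= 1
            else:
                r = _settle_scan(x[v], y[v], sex[v], window, True,
                                 baseq_p, digest, qmul, patch, occ, occ_af,
                                 ring_dy, ring_dx, ring_ptr, P)
            if r > 0:
                tx[v] = x[v]
                ty[v] = y[v]
                tr[v] = r
                # insert at most once per day: re-insertion would cycle the list
                if th_in[v] == 0:
                    _hash_insert(th_heads, th_next, bx_n, tx[v], ty[v], v)
                    th_in[v] = 1
            else:
                _disperse_move(v, alive, sex, age, x, y, nursing, l_alive,
                               l_mother, l_x, l_y, l_born, l_size,
                               live_l, n_live_l_arr[0],
                               occ, occ_af, barrier, baseq_p, patch, heading,
                               deaths, t, adult, disp_left[v] > 0, P)
        elif alive[v] == 1:
            # daily within-home-range movement: uniform point in the range;
            # males range out to the male maximum radius (V7), females to
            # their territory radius
            H2, W2 = occ.shape
            wr = P[P_MALE_RANGE_R] if sex[v] == 1 else float(tr[v])
            for _try in range(4):
                ang = np.random.random() * 2.0 * np.pi
                rad = wr * np.sqrt(np.random.random())
                wx = int(round(tx[v] + rad * np.cos(ang)))
                wy = int(round(ty[v] + rad * np.sin(ang)))
                if 0 <= wx < W2 and 0 <= wy < H2 and barrier[wy, wx] == 0:
                    if wx != x[v] or wy != y[v]:
                        occ[y[v], x[v]] -= 1
                        occ[wy, wx] += 1
                        if sex[v] == 0 and adult:
                            occ_af[y[v], x[v]] -= 1
                            occ_af[wy, wx] += 1
                        x[v] = wx
                        y[v] = wy
                    break


@njit(cache=True)
def _wean_litters(t, alive, sex, age, x, y, natal_x, natal_y, lifespan,
                  tx, ty, tr, uid, preg_due, nursing, heading, disp_left,
                  uid_counter,
                  l_alive, l_mother, l_x, l_y, l_born, l_size,
                  occ, overflow, free_a_arr, ring_dy, ring_dx, ring_ptr, P):
    NL = l_alive.shape[0]
    wean_age = int(P[P_WEAN_AGE])
    for li in range(NL):
        if l_alive[li] == 1 and t - l_born[li] >= wean_age:
            # natal dispersal is density-dependent: weanlings from crowded
            # natal sites may express the long-dispersal phenotype
            crowded = _count_occ_disk(
                l_x[li], l_y[li], int(P[P_F_MIN_R]), occ,
                ring_dy, ring_dx, ring_ptr) >= P[P_DENS_THRESH] * P[P_DD_GATE]
            for _k in range(l_size[li]):
                ai = _find_free(alive, free_a_arr[0])
                if ai < 0:
                    overflow[0] += 1
                    break
                free_a_arr[0] = ai + 1
                alive[ai] = 1
                sex[ai] = 1 if np.random.random() < 0.5 else 0
                age[ai] = wean_age
                x[ai] = l_x[li]
                y[ai] = l_y[li]
                natal_x[ai] = l_x[li]
                natal_y[ai] = l_y[li]
                ls = np.random.normal(P[P_LIFE_MEAN_D], P[P_LIFE_SD_D])
                lifespan[ai] = max(1, int(round(ls)))
                tx[ai] = 0
                ty[ai] = 0
                tr[ai] = 0
                preg_due[ai] = -1
                nursing[ai] = -1
                heading[ai] = np.random.random() * 2.0 * np.pi
                if crowded and np.random.random() < P[P_P_FAR]:
                    lo = int(P[P_DISP_MIN_D])
                    hi = int(P[P_DISP_MAX_D])
                    dur = np.random.randint(lo, hi + 1)
                    if sex[ai] == 1:
                        dur = int(round(dur * P[P_DISP_MALE_X]))
                    disp_left[ai] = dur
                else:
                    disp_left[ai] = 0
                uid[ai] = uid_counter[0]
                uid_counter[0] += 1
                occ[y[ai], x[ai]] += 1
                overflow[1 + sex[ai]] += 1
            l_alive[li] = 0
            m = l_mother[li]
            if m >= 0 and alive[m] == 1 and nursing[m] == li:
                nursing[m] = -1


@njit(cache=True)
def _predator_day(t, doy, alive, sex, age, x, y, nursing,
                  l_alive, occ, occ_af,
                  pd_alive, pd_x, pd_y, pd_unsucc, pd_repro_year,
                  ah_heads, ah_next, deaths, PP, P,
                  hab_xs, hab_ys, baseq, patch,
                  ring_dy, ring_dx, ring_ptr, bx_n, by_n):
    H, W = occ.shape
    N = alive.shape[0]
    nbins = bx_n * by_n
    for b in range(nbins):
        ah_heads[b] = -1
    for i in range(N):
        if alive[i] == 1:
            _hash_insert(ah_heads, ah_next, bx_n, x[i], y[i], i)
    year = t // 365
    hr = int(PP[Q_HOME_R])
    NP = pd_alive.shape[0]
    # spring immigration from the regional pool keeps the predator guild
    # from going locally extinct between cycles
    if doy == 100:
        n_now = 0
        for pi in range(NP):
            if pd_alive[pi] == 1:
                n_now += 1
        need = int(PP[Q_IMMIGRATION]) - n_now
        for _k in range(max(0, need)):
            for pj in range(NP):
                if pd_alive[pj] == 0:
                    h = np.random.randint(0, hab_xs.shape[0])
                    pd_alive[pj] = 1
                    pd_x[pj] = hab_xs[h]
                    pd_y[pj] = hab_ys[h]
                    pd_unsucc[pj] = 0
                    pd_repro_year[pj] = year
                    break
    fem_min = int(P[P_FEMALE_MIN_AGE])
    n_pred = 0
    for pi in range(NP):
        if pd_alive[pi] == 0:
            continue
        local = _count_occ_disk(pd_x[pi], pd_y[pi], hr, occ,
                                ring_dy, ring_dx, ring_ptr)
        kills = 0
        cap_k = int(PP[Q_KILL_CAP])
        if local > 0 and cap_k > 0:
            bx0 = pd_x[pi] // HASH_BS
            by0 = pd_y[pi] // HASH_BS
            brad = hr // HASH_BS + 1
            for by in range(max(0, by0 - brad), min(by_n, by0 + brad + 1)):
                if kills >= cap_k:
                    break
                for bx in range(max(0, bx0 - brad), min(bx_n, bx0 + brad + 1)):
                    if kills >= cap_k:
                        break
                    u = ah_heads[by * bx_n + bx]
                    while u >= 0 and kills < cap_k:
                        if alive[u] == 1:
                            d = np.hypot(float(x[u] - pd_x[pi]),
                                         float(y[u] - pd_y[pi]))
                            if d <= hr:
                                _kill_agent(u, D_PREDATION, alive, sex, age,
                                            x, y, nursing, l_alive,
                                            occ, occ_af, deaths, fem_min)
                                kills += 1
                        u = ah_next[u]
        if local < PP[Q_SURVIVE_THRESH]:
            pd_unsucc[pi] += 1
        else:
            pd_unsucc[pi] = 0
        if pd_unsucc[pi] >= PP[Q_STARVE_DAYS]:
            pd_alive[pi] = 0
            continue
        if pd_unsucc[pi] >= PP[Q_UNSUCC_DISP]:
            # short-range dispersal, biased to stay in forage-bearing habitat
            for _try in range(6):
                ang = np.random.random() * 2.0 * np.pi
                cx = int(round(pd_x[pi] + PP[Q_DISP_STEP] * np.cos(ang)))
                cy = int(round(pd_y[pi] + PP[Q_DISP_STEP] * np.sin(ang)))
                if 0 <= cx < W and 0 <= cy < H:
                    if baseq[patch[cy, cx]] > 0.0 or _try == 5:
                        pd_x[pi] = cx
                        pd_y[pi] = cy
                        break
        if (PP[Q_REPRO_START] <= doy <= PP[Q_REPRO_END]
                and local >= PP[Q_REPRO_THRESH]
                and pd_repro_year[pi] < year):
            pd_repro_year[pi] = year
            born = 0
            for pj in range(NP):
                if born >= int(PP[Q_LITTER]):
                    break
                if pd_alive[pj] == 0:
                    # offspring disperse to their own hunting grounds
                    h = np.random.randint(0, hab_xs.shape[0])
                    pd_alive[pj] = 1
                    pd_x[pj] = hab_xs[h]
                    pd_y[pj] = hab_ys[h]
                    pd_unsucc[pj] = 0
                    pd_repro_year[pj] = year
                    born += 1
    for pi in range(NP):
        if pd_alive[pi] == 1:
            n_pred += 1
    return n_pred


@njit(cache=True)
def _record_day(t, n_pred, alive, sex, age, x, y, natal_x, natal_y, uid,
                patch, trap_map, capture_start,
                cap_day, cap_trap, cap_uid, cap_age, cap_sex,
                cap_natal_x, cap_natal_y, cap_x, cap_y, cap_count,
                out_counts, out_patch_n, record_patch,
                snap_idx, snap_age, snap_sex, P):
    N = alive.shape[0]
    fem_min = int(P[P_FEMALE_MIN_AGE])
    male_min = int(P[P_MALE_MIN_AGE])
    n_m = 0
    n_f = 0
    n_am = 0
    n_af = 0
    si = snap_idx[t]
    for i in range(N):
        if alive[i] == 0:
            continue
        if sex[i] == 0:
            n_f += 1
            if age[i] >= fem_min:
                n_af += 1
        else:
            n_m += 1
            if age[i] >= male_min:
                n_am += 1
        if record_patch == 1:
            out_patch_n[t, patch[y[i], x[i]]] += 1
        if capture_start >= 0 and t >= capture_start:
            ti = trap_map[y[i], x[i]]
            if ti >= 0 and cap_count[0] < cap_day.shape[0]:
                c = cap_count[0]
                cap_day[c] = t
                cap_trap[c] = ti
                cap_uid[c] = uid[i]
                cap_age[c] = age[i]
                cap_sex[c] = sex[i]
                cap_natal_x[c] = natal_x[i]
                cap_natal_y[c] = natal_y[i]
                cap_x[c] = x[i]
                cap_y[c] = y[i]
                cap_count[0] += 1
        if si >= 0:
            snap_age[si, i] = age[i]
            snap_sex[si, i] = sex[i]
    out_counts[t, 0] = n_m
    out_counts[t, 1] = n_f
    out_counts[t, 2] = n_am
    out_counts[t, 3] = n_af
    out_counts[t, 4] = n_pred


@njit(cache=True)
def run_days(
    t0, t1,
    # landscape
    patch, baseq_p, growth_p, qmul, barrier,
    # vegetation state
    veg_ring, veg_total, veg_head_arr, digest,
    # per-day drivers (absolute day indexed)
    growth_ok, conceive_ok, vole_immigration,
    # vole state
    alive, sex, age, x, y, natal_x, natal_y, lifespan,
    tx, ty, tr, uid, preg_due, nursing, heading, disp_left, uid_counter,
    # litters
    l_alive, l_mother, l_x, l_y, l_born, l_size,
    # occupancy
    occ, occ_af,
    # predators
    preds_on, pred_start, pd_alive, pd_x, pd_y, pd_unsucc, pd_repro_year, PP,
    hab_xs, hab_ys,
    # traps
    trap_map, capture_start,
    cap_day, cap_trap, cap_uid, cap_age, cap_sex,
    cap_natal_x, cap_natal_y, cap_x, cap_y, cap_count,
    # outputs
    out_counts, out_patch_n, record_patch, deaths, overflow,
    snap_idx, snap_age, snap_sex,
    # scratch hash arrays
    th_heads, th_next, ah_heads, ah_next,
    # params & geometry
    P, ring_dy, ring_dx, ring_ptr,
):
    H, W = patch.shape
    N = alive.shape[0]
    NL = l_alive.shape[0]
    bx_n = (W + HASH_BS - 1) // HASH_BS
    by_n = (H + HASH_BS - 1) // HASH_BS
    nbins = bx_n * by_n
    order = np.empty(N, dtype=np.int32)
    th_in = np.zeros(N, dtype=np.uint8)
    live_l = np.empty(NL, dtype=np.int32)
    n_live_l_arr = np.zeros(1, dtype=np.int64)
    free_a_arr = np.zeros(1, dtype=np.int64)
    free_l_arr = np.zeros(1, dtype=np.int64)

    for t in range(t0, t1):
        doy = t % 365 + 1
        window = conceive_ok[t] == 1

        _vegetation_day(veg_ring, veg_total, veg_head_arr, digest,
                        growth_p, growth_ok[t] == 1, P[P_BIOMASS_DECAY])

        # territory spatial hash
        for b in range(nbins):
            th_heads[b] = -1
        for i in range(N):
            th_in[i] = 0
        for i in range(N):
            if alive[i] == 1 and tr[i] > 0:
                _hash_insert(th_heads, th_next, bx_n, tx[i], ty[i], i)
                th_in[i] = 1

        # compact list of live litters (for infanticide encounters)
        n_live_l_arr[0] = 0
        for li in range(NL):
            if l_alive[li] == 1:
                live_l[n_live_l_arr[0]] = li
                n_live_l_arr[0] += 1

        _vole_loop(t, window, growth_ok[t] == 1, baseq_p, digest, qmul,
                   patch, barrier,
                   alive, sex, age, x, y, natal_x, natal_y, lifespan,
                   tx, ty, tr, uid, preg_due, nursing, heading, disp_left,
                   l_alive, l_mother, l_x, l_y, l_born, l_size,
                   live_l, n_live_l_arr,
                   occ, occ_af, th_heads, th_next, th_in, order, deaths,
                   overflow, free_l_arr, P, ring_dy, ring_dx, ring_ptr,
                   bx_n, by_n)

        # spring arrival of a few immigrant adults from the regional pool
        if vole_immigration > 0 and doy == 95 and t >= 365:
            for _imm in range(vole_immigration):
                ai = _find_free(alive, 0)
                if ai < 0:
                    break
                h = np.random.randint(0, hab_xs.shape[0])
                alive[ai] = 1
                sex[ai] = _imm % 2
                age[ai] = 60 + np.random.randint(0, 60)
                x[ai] = hab_xs[h]
                y[ai] = hab_ys[h]
                natal_x[ai] = x[ai]
                natal_y[ai] = y[ai]
                ls = np.random.normal(P[P_LIFE_MEAN_D], P[P_LIFE_SD_D])
                lifespan[ai] = max(age[ai] + 1, int(round(ls)))
                tx[ai] = 0
                ty[ai] = 0
                tr[ai] = 0
                preg_due[ai] = -1
                nursing[ai] = -1
                heading[ai] = np.random.random() * 2.0 * np.pi
                disp_left[ai] = 0
                uid[ai] = uid_counter[0]
                uid_counter[0] += 1
                occ[y[ai], x[ai]] += 1
                if sex[ai] == 0 and age[ai] >= int(P[P_FEMALE_MIN_AGE]):
                    occ_af[y[ai], x[ai]] += 1

        _wean_litters(t, alive, sex, age, x, y, natal_x, natal_y, lifespan,
                      tx, ty, tr, uid, preg_due, nursing, heading, disp_left,
                      uid_counter,
                      l_alive, l_mother, l_x, l_y, l_born, l_size,
                      occ, overflow, free_a_arr, ring_dy, ring_dx, ring_ptr, P)

        n_pred = 0
        if preds_on == 1 and t >= pred_start:
            n_pred = _predator_day(t, doy, alive, sex, age, x, y, nursing,
                                   l_alive, occ, occ_af,
                                   pd_alive, pd_x, pd_y, pd_unsucc,
                                   pd_repro_year, ah_heads, ah_next,
                                   deaths, PP, P, hab_xs, hab_ys,
                                   baseq_p, patch,
                                   ring_dy, ring_dx, ring_ptr, bx_n, by_n)

        _record_day(t, n_pred, alive, sex, age, x, y, natal_x, natal_y, uid,
                    patch, trap_map, capture_start,
                    cap_day, cap_trap, cap_uid, cap_age, cap_sex,
                    cap_natal_x, cap_natal_y, cap_x, cap_y, cap_count,
                    out_counts, out_patch_n, record_patch,
                    snap_idx, snap_age, snap_sex, P)
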