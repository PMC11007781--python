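"""Numba-compiled inner loops: pulse-echo simulation, delay-and-sum, NCC matching.

All positions are in mm; times in seconds; ``c_mms`` is the sound speed in
mm/s.  These functions are private plumbing — the public API lives in the
module that wraps each of them.
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def simulate_event_rf(
    scat_pos,
    scat_amp,
    scat_norm,
    tx_pos,
    tx_norm,
    tx_apod,
    tx_delays,
    rx_pos,
    rx_norm,
    t0,
    n_t,
    fs,
    c_mms,
    f0,
    sigma_t,
    dir_power,
    spec_power,
    diffuse_fraction,
):
    """Linear scattering forward model for one transmit event, one receive probe.

    Transmit arrival at a scatterer is the first arrival over elements
    (element delay + travel time); the transmit amplitude uses the directivity
    and apodization of that first-arriving element.  Each echo deposits a
    Gaussian-modulated cosine pulse at the round-trip time.

    Scatterers with a non-zero ``scat_norm`` scatter specularly: their echo is
    weighted by ``diffuse_fraction + (1 - diffuse_fraction) * |n . b|^spec_power``
    where ``b`` is the bisector of the directions to the transmit and receive
    elements (mirror law for a bistatic geometry; symmetric in tx/rx, so
    reciprocity is preserved).  Zero-normal scatterers are isotropic.
    """
    n_s = scat_pos.shape[0]
    n_tx = tx_pos.shape[0]
    n_rx = rx_pos.shape[0]
    t_tx = np.empty(n_s)
    a_tx = np.empty(n_s)
    b_tx = np.empty(n_s, dtype=np.int64)
    for s in range(n_s):
        best = 1e30
        bj = 0
        for j in range(n_tx):
            dx = scat_pos[s, 0] - tx_pos[j, 0]
            dz = scat_pos[s, 1] - tx_pos[j, 1]
            t = tx_delays[j] + math.sqrt(dx * dx + dz * dz) / c_mms
            if t < best:
                best = t
                bj = j
        t_tx[s] = best
        b_tx[s] = bj
        dx = scat_pos[s, 0] - tx_pos[bj, 0]
        dz = scat_pos[s, 1] - tx_pos[bj, 1]
        dist = math.sqrt(dx * dx + dz * dz)
        if dist > 0.0:
            ca = (dx * tx_norm[bj, 0] + dz * tx_norm[bj, 1]) / dist
        else:
            ca = 1.0
        if ca < 0.0:
            ca = 0.0
        a_tx[s] = scat_amp[s] * tx_apod[bj] * ca**dir_power

    out = np.zeros((n_rx, n_t))
    half_w = int(4.0 * sigma_t * fs) + 1
    inv_2s2 = 1.0 / (2.0 * sigma_t * sigma_t)
    for i in range(n_rx):
        for s in range(n_s):
            a = a_tx[s]
            if a == 0.0:
                continue
            dx = scat_pos[s, 0] - rx_pos[i, 0]
            dz = scat_pos[s, 1] - rx_pos[i, 1]
            dist = math.sqrt(dx * dx + dz * dz)
            if dist > 0.0:
                ca = (dx * rx_norm[i, 0] + dz * rx_norm[i, 1]) / dist
            else:
                ca = 1.0
            if ca <= 0.0:
                continue
            amp = a * ca**dir_power
            if scat_norm[s, 0] != 0.0 or scat_norm[s, 1] != 0.0:
                # mirror-law lobe about the scatterer normal: bisector of the
                # unit directions to the first-arrival tx element and rx element
                j = b_tx[s]
                ux = tx_pos[j, 0] - scat_pos[s, 0]
                uz = tx_pos[j, 1] - scat_pos[s, 1]
                un = math.sqrt(ux * ux + uz * uz)
                if un > 0.0:
                    ux /= un
                    uz /= un
                bx = ux - dx / dist
                bz = uz - dz / dist
                bn = math.sqrt(bx * bx + bz * bz)
                if bn > 0.0:
                    cs = abs(bx * scat_norm[s, 0] + bz * scat_norm[s, 1]) / bn
                else:
                    cs = 1.0
                amp *= diffuse_fraction + (1.0 - diffuse_fraction) * cs**spec_power
            tau = t_tx[s] + dist / c_mms
            nc = int((tau - t0) * fs)
            n_lo = nc - half_w
            if n_lo < 0:
                n_lo = 0
            n_hi = nc + half_w + 1
            if n_hi > n_t:
                n_hi = n_t
            for n in range(n_lo, n_hi):
                tr = t0 + n / fs - tau
                out[i, n] += amp * math.exp(-tr * tr * inv_2s2) * math.cos(TWO_PI * f0 * tr)
    return out


@njit(cache=True)
def first_arrival_times(nodes, el_pos, delays, c_mms):
    """Minimum of (element delay + element->node travel time), per node."""
    n_nodes = nodes.shape[0]
    n_el = el_pos.shape[0]
    out = np.empty(n_nodes)
    for k in range(n_nodes):
        best = 1e30
        for j in range(n_el):
            dx = nodes[k, 0] - el_pos[j, 0]
            dz = nodes[k, 1] - el_pos[j, 1]
            t = delays[j] + math.sqrt(dx * dx + dz * dz) / c_mms
            if t < best:
                best = t
        out[k] = best
    return out


@njit(cache=True)
def das_sum(iq, rx_pos, rx_norm, nodes, t_tx, t0, fs, f0, c_mms, cos_min):
    """Delay-and-sum of baseband channel data onto arbitrary nodes.

    Linear interpolation between IQ samples plus carrier phase rotation
    ``exp(+j 2 pi f0 tau)``; elements outside the acceptance cone
    (``cos(angle) < cos_min``) or delays outside the record contribute zero.
    """
    n_nodes = nodes.shape[0]
    n_el = rx_pos.shape[0]
    n_t = iq.shape[1]
    out = np.zeros(n_nodes, dtype=np.complex128)
    for k in range(n_nodes):
        acc = 0.0 + 0.0j
        for i in range(n_el):
            dx = nodes[k, 0] - rx_pos[i, 0]
            dz = nodes[k, 1] - rx_pos[i, 1]
            dist = math.sqrt(dx * dx + dz * dz)
            if dist <= 0.0:
                continue
            ca = (dx * rx_norm[i, 0] + dz * rx_norm[i, 1]) / dist
            if ca < cos_min:
                continue
            tau = t_tx[k] + dist / c_mms
            fidx = (tau - t0) * fs
            i0 = int(math.floor(fidx))
            if i0 < 0 or i0 + 1 >= n_t:
                continue
            w = fidx - i0
            s = iq[i, i0] * (1.0 - w) + iq[i, i0 + 1] * w
            ph = TWO_PI * f0 * tau
            acc += s * complex(math.cos(ph), math.sin(ph))
        out[k] = acc
    return out


@njit(cache=True, inline="always")
def _parabolic_offset(cm, c0, cp):
    denom = cm - 2.0 * c0 + cp
    if denom == 0.0:
        return 0.0
    off = (cm - cp) / (2.0 * denom)
    if off > 0.5:
        off = 0.5
    elif off < -0.5:
        off = -0.5
    return off


@njit(cache=True)
def ncc_block_match(
    ref,
    mov,
    node_ax,
    node_lat,
    khalf_ax,
    khalf_lat,
    lag_ax,
    lag_lat,
    seed_ax,
    seed_lat,
    zero_mean,
):
    """Normalized cross-correlation block matching at a list of grid nodes.

    ``ref``/``mov`` are (n_axial, n_lateral) real images.  For node ``n`` the
    kernel is ``ref`` centred at (node_ax, node_lat) with half sizes
    ``khalf_*[n]``; it is slid over ``mov`` at integer lags
    ``seed_*[n] +/- lag_*``.  Correlation is zero-mean when ``zero_mean`` is
    true (envelope pass) and raw otherwise (RF pass).  The integer argmax is
    refined by parabolic interpolation per axis; ties prefer the
    smallest-magnitude lag (scan order guarantees this).  Returns per-node
    (du_ax, du_lat) in samples, peak correlation, and validity.
    """
    n_nodes = node_ax.shape[0]
    n_ax, n_lat = ref.shape
    du_ax = np.zeros(n_nodes)
    du_lat = np.zeros(n_nodes)
    quality = np.zeros(n_nodes)
    valid = np.zeros(n_nodes, dtype=np.bool_)

    n_la = 2 * lag_ax + 1
    n_ll = 2 * lag_lat + 1
    # lag scan order: 0, -1, +1, -2, +2, ... so ties keep the smallest lag
    order_ax = np.empty(n_la, dtype=np.int64)
    order_lat = np.empty(n_ll, dtype=np.int64)
    order_ax[0] = 0
    k = 1
    for a in range(1, lag_ax + 1):
        order_ax[k] = -a
        k += 1
        order_ax[k] = a
        k += 1
    order_lat[0] = 0
    k = 1
    for a in range(1, lag_lat + 1):
        order_lat[k] = -a
        k += 1
        order_lat[k] = a
        k += 1

    cc = np.empty((n_la, n_ll))
    for n in range(n_nodes):
        ia = node_ax[n]
        il = node_lat[n]
        ka = khalf_ax[n]
        kl = khalf_lat[n]
        sa = seed_ax[n]
        sl = seed_lat[n]
        # window bounds in ref
        a0 = ia - ka
        a1 = ia + ka
        l0 = il - kl
        l1 = il + kl
        if a0 < 0 or a1 >= n_ax or l0 < 0 or l1 >= n_lat:
            continue
        # moving window extremes in mov
        if (
            a0 + sa - lag_ax < 0
            or a1 + sa + lag_ax >= n_ax
            or l0 + sl - lag_lat < 0
            or l1 + sl + lag_lat >= n_lat
        ):
            continue

        # reference kernel statistics
        r_sum = 0.0
        r_sum2 = 0.0
        npx = (2 * ka + 1) * (2 * kl + 1)
        for a in range(a0, a1 + 1):
            for l in range(l0, l1 + 1):
                v = ref[a, l]
                r_sum += v
                r_sum2 += v * v
        if zero_mean:
            r_mean = r_sum / npx
            r_var = r_sum2 - r_sum * r_sum / npx
        else:
            r_mean = 0.0
            r_var = r_sum2
        if r_var <= 0.0:
            valid[n] = True
            quality[n] = 0.0
            continue

        best = -2.0
        best_i = 0
        best_j = 0
        for oi in range(n_la):
            da = order_ax[oi] + sa
            for oj in range(n_ll):
                dl = order_lat[oj] + sl
                num = 0.0
                m_sum = 0.0
                m_sum2 = 0.0
                for a in range(a0, a1 + 1):
                    for l in range(l0, l1 + 1):
                        rv = ref[a, l]
                        mv = mov[a + da, l + dl]
                        num += rv * mv
                        m_sum += mv
                        m_sum2 += mv * mv
                if zero_mean:
                    num -= r_mean * m_sum
                    m_var = m_sum2 - m_sum * m_sum / npx
                else:
                    m_var = m_sum2
                if m_var <= 0.0:
                    c = 0.0
                else:
                    c = num / math.sqrt(r_var * m_var)
                ii = order_ax[oi] + lag_ax
                jj = order_lat[oj] + lag_lat
                cc[ii, jj] = c
                if c > best:
                    best = c
                    best_i = ii
                    best_j = jj

        # sub-sample refinement; skipped on a perfect integer-lag match, where
        # the parabolic fit would only add asymmetric-window bias
        off_a = 0.0
        off_l = 0.0
        refine = best < 1.0 - 1e-12
        if refine and 0 < best_i < n_la - 1:
            off_a = _parabolic_offset(cc[best_i - 1, best_j], cc[best_i, best_j], cc[best_i + 1, best_j])
        if refine and 0 < best_j < n_ll - 1:
            off_l = _parabolic_offset(cc[best_i, best_j - 1], cc[best_i, best_j], cc[best_i, best_j + 1])
        du_ax[n] = sa + best_i - lag_ax + off_a
        du_lat[n] = sl + best_j - lag_lat + off_l
        quality[n] = best
        valid[n] = True
    return du_ax, du_lat, quality, valid


@njit(cache=True)
def simulate_event_rf_full(
    scat_pos,
    scat_amp,
    scat_norm,
    tx_pos,
    tx_norm,
    tx_apod,
    tx_delays,
    rx_pos,
    rx_norm,
    t0,
    n_t,
    fs,
    c_mms,
    f0,
    sigma_t,
    dir_power,
    spec_power,
    diffuse_fraction,
):
    """Exact element-pair summation forward model (reference, O(n_tx) slower).

    Every (tx element, scatterer, rx element) path contributes a pulse at
    ``delay_j + d_j/c + d_i/c`` weighted by apodization and both elements'
    directivities — the transmit wavefront is the true apodized element sum,
    so acoustic reciprocity holds pair by pair.
    """
    n_s = scat_pos.shape[0]
    n_tx = tx_pos.shape[0]
    n_rx = rx_pos.shape[0]
    out = np.zeros((n_rx, n_t))
    half_w = int(4.0 * sigma_t * fs) + 1
    inv_2s2 = 1.0 / (2.0 * sigma_t * sigma_t)
    t_txs = np.empty(n_tx)
    a_txs = np.empty(n_tx)
    for s in range(n_s):
        amp_s = scat_amp[s]
        if amp_s == 0.0:
            continue
        for j in range(n_tx):
            dx = scat_pos[s, 0] - tx_pos[j, 0]
            dz = scat_pos[s, 1] - tx_pos[j, 1]
            dist = math.sqrt(dx * dx + dz * dz)
            t_txs[j] = tx_delays[j] + dist / c_mms
            if dist > 0.0:
                ca = (dx * tx_norm[j, 0] + dz * tx_norm[j, 1]) / dist
            else:
                ca = 1.0
            a_txs[j] = tx_apod[j] * ca**dir_power if ca > 0.0 else 0.0
        for i in range(n_rx):
            dx = scat_pos[s, 0] - rx_pos[i, 0]
            dz = scat_pos[s, 1] - rx_pos[i, 1]
            dist = math.sqrt(dx * dx + dz * dz)
            if dist > 0.0:
                ca = (dx * rx_norm[i, 0] + dz * rx_norm[i, 1]) / dist
            else:
                ca = 1.0
            if ca <= 0.0:
                continue
            t_rx = dist / c_mms
            a_rx = amp_s * ca**dir_power
            for j in range(n_tx):
                a = a_rx * a_txs[j]
                if a == 0.0:
                    continue
                if scat_norm[s, 0] != 0.0 or scat_norm[s, 1] != 0.0:
                    ux = tx_pos[j, 0] - scat_pos[s, 0]
                    uz = tx_pos[j, 1] - scat_pos[s, 1]
                    un = math.sqrt(ux * ux + uz * uz)
                    if un > 0.0:
                        ux /= un
                        uz /= un
                    bx = ux + (rx_pos[i, 0] - scat_pos[s, 0]) / dist
                    bz = uz + (rx_pos[i, 1] - scat_pos[s, 1]) / dist
                    bn = math.sqrt(bx * bx + bz * bz)
                    if bn > 0.0:
                        cs = abs(bx * scat_norm[s, 0] + bz * scat_norm[s, 1]) / bn
                    else:
                        cs = 1.0
                    a *= diffuse_fraction + (1.0 - diffuse_fraction) * cs**spec_power
                tau = t_txs[j] + t_rx
                nc = int((tau - t0) * fs)
                n_lo = nc - half_w
                if n_lo < 0:
                    n_lo = 0
                n_hi = nc + half_w + 1
                if n_hi > n_t:
                    n_hi = n_t
                for n in range(n_lo, n_hi):
                    tr = t0 + n / fs - tau
                    out[i, n] += a * math.exp(-tr * tr * inv_2s2) * math.cos(TWO_PI * f0 * tr)
    return out
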