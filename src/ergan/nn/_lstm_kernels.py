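"""LSTM recurrence kernels.

The time loop of the LSTM forward/backward pass is the hot spot of GAN
training, so it is compiled with numba when available; the pure-numpy
implementations below are the reference semantics (identical operation
order, hence bit-identical results) and the fallback.

Gate order in the packed 4H axis: input, forget, cell, output.
"""

from __future__ import annotations

import numpy as np


def _lstm_forward_np(xw: np.ndarray, wh: np.ndarray, reverse: bool):
    B, T, four_h = xw.shape
    H = four_h // 4
    i_c = np.empty((B, T, H))
    f_c = np.empty((B, T, H))
    g_c = np.empty((B, T, H))
    o_c = np.empty((B, T, H))
    c_c = np.empty((B, T, H))
    tc_c = np.empty((B, T, H))
    h_c = np.empty((B, T, H))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for k in range(T):
        t = T - 1 - k if reverse else k
        gates = xw[:, t, :] + h @ wh
        i = 1.0 / (1.0 + np.exp(-gates[:, :H]))
        f = 1.0 / (1.0 + np.exp(-gates[:, H : 2 * H]))
        g = np.tanh(gates[:, 2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-gates[:, 3 * H :]))
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        i_c[:, t], f_c[:, t], g_c[:, t], o_c[:, t] = i, f, g, o
        c_c[:, t], tc_c[:, t], h_c[:, t] = c, tc, h
    return i_c, f_c, g_c, o_c, c_c, tc_c, h_c


def _lstm_backward_np(
    grad_h: np.ndarray,
    x: np.ndarray,
    wx: np.ndarray,
    wh: np.ndarray,
    i_c: np.ndarray,
    f_c: np.ndarray,
    g_c: np.ndarray,
    o_c: np.ndarray,
    c_c: np.ndarray,
    tc_c: np.ndarray,
    h_c: np.ndarray,
    reverse: bool,
):
    B, T, H = i_c.shape
    dx = np.zeros_like(x)
    dwx = np.zeros_like(wx)
    dwh = np.zeros_like(wh)
    db = np.zeros(4 * H)
    dh_carry = np.zeros((B, H))
    dc_carry = np.zeros((B, H))
    da = np.empty((B, 4 * H))
    zeros = np.zeros((B, H))
    for k in range(T - 1, -1, -1):
        t = T - 1 - k if reverse else k
        t_prev = (T - k if reverse else k - 1) if k > 0 else -1
        i, f, g, o = i_c[:, t], f_c[:, t], g_c[:, t], o_c[:, t]
        tc = tc_c[:, t]
        c_prev = c_c[:, t_prev] if t_prev >= 0 else zeros
        h_prev = h_c[:, t_prev] if t_prev >= 0 else zeros
        dh = grad_h[:, t, :] + dh_carry
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_carry
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_carry = dc * f
        da[:, :H] = di * i * (1.0 - i)
        da[:, H : 2 * H] = df * f * (1.0 - f)
        da[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
        da[:, 3 * H :] = do * o * (1.0 - o)
        dx[:, t, :] = da @ wx.T
        dwx += x[:, t, :].T @ da
        dwh += h_prev.T @ da
        db += da.sum(axis=0)
        dh_carry = da @ wh.T
    return dx, dwx, dwh, db


try:  # pragma: no cover - exercised indirectly
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _lstm_forward_nb(xw, wh, reverse):
        B, T, four_h = xw.shape
        H = four_h // 4
        i_c = np.empty((B, T, H))
        f_c = np.empty((B, T, H))
        g_c = np.empty((B, T, H))
        o_c = np.empty((B, T, H))
        c_c = np.empty((B, T, H))
        tc_c = np.empty((B, T, H))
        h_c = np.empty((B, T, H))
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        for k in range(T):
            t = T - 1 - k if reverse else k
            gates = np.ascontiguousarray(xw[:, t, :]) + np.dot(h, wh)
            for b in range(B):
                for j in range(H):
                    i = 1.0 / (1.0 + np.exp(-gates[b, j]))
                    f = 1.0 / (1.0 + np.exp(-gates[b, H + j]))
                    g = np.tanh(gates[b, 2 * H + j])
                    o = 1.0 / (1.0 + np.exp(-gates[b, 3 * H + j]))
                    cc = f * c[b, j] + i * g
                    tc = np.tanh(cc)
                    c[b, j] = cc
                    h[b, j] = o * tc
                    h_c[b, t, j] = h[b, j]
                    i_c[b, t, j] = i
                    f_c[b, t, j] = f
                    g_c[b, t, j] = g
                    o_c[b, t, j] = o
                    c_c[b, t, j] = cc
                    tc_c[b, t, j] = tc
        return i_c, f_c, g_c, o_c, c_c, tc_c, h_c

    @numba.njit(cache=True, fastmath=True)
    def _lstm_backward_nb(grad_h, x, wx, wh, i_c, f_c, g_c, o_c, c_c, tc_c, h_c, reverse):
        B, T, H = i_c.shape
        I = x.shape[2]
        dx = np.zeros((B, T, I))
        dwx = np.zeros((I, 4 * H))
        dwh = np.zeros((H, 4 * H))
        db = np.zeros(4 * H)
        dh_carry = np.zeros((B, H))
        dc_carry = np.zeros((B, H))
        da = np.empty((B, 4 * H))
        wxT = np.ascontiguousarray(wx.T)
        whT = np.ascontiguousarray(wh.T)
        for k in range(T - 1, -1, -1):
            t = T - 1 - k if reverse else k
            t_prev = (T - k if reverse else k - 1) if k > 0 else -1
            for b in range(B):
                for j in range(H):
                    i = i_c[b, t, j]
                    f = f_c[b, t, j]
                    g = g_c[b, t, j]
                    o = o_c[b, t, j]
                    tc = tc_c[b, t, j]
                    c_prev = c_c[b, t_prev, j] if t_prev >= 0 else 0.0
                    dh = grad_h[b, t, j] + dh_carry[b, j]
                    do = dh * tc
                    dc = dh * o * (1.0 - tc * tc) + dc_carry[b, j]
                    di = dc * g
                    df = dc * c_prev
                    dg = dc * i
                    dc_carry[b, j] = dc * f
                    da[b, j] = di * i * (1.0 - i)
                    da[b, H + j] = df * f * (1.0 - f)
                    da[b, 2 * H + j] = dg * (1.0 - g * g)
                    da[b, 3 * H + j] = do * o * (1.0 - o)
            dx[:, t, :] = np.dot(da, wxT)
            xt = np.ascontiguousarray(x[:, t, :])
            dwx += np.dot(xt.T, da)
            if t_prev >= 0:
                hp = np.ascontiguousarray(h_c[:, t_prev, :])
                dwh += np.dot(hp.T, da)
            for b in range(B):
                for j in range(4 * H):
                    db[j] += da[b, j]
            dh_carry = np.dot(da, whT)
        return dx, dwx, dwh, db

    lstm_forward = _lstm_forward_nb
    lstm_backward = _lstm_backward_nb
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    lstm_forward = _lstm_forward_np
    lstm_backward = _lstm_backward_np
    HAVE_NUMBA = False
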