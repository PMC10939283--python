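"""Compiled simulation kernel (numba) with uniform-grid neighbor search.

Mirrors the numpy reference path in :mod:`.dynamics` step for step: the
same semi-implicit Euler update, boundary rule, reroute schedule and
dwell bookkeeping, consuming the same pre-drawn random streams.  The
pair interactions run over a linked-cell grid whose cell size is the
largest interaction cutoff, which keeps the cost O(n) at typical crowd
densities; a single-cell grid degenerates gracefully to the brute-force
pair loop.  Forces are accumulated in a different order than the
vectorized path, so trajectories agree to float tolerance, not bitwise.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .contacts import ContactDefinition, _DWELL_EPS

__all__ = ["run_compiled"]


@njit(cache=True)
def _grid_build(x, cell, ncell, head, nxt):
    n = x.shape[0]
    for cx in range(ncell):
        for cy in range(ncell):
            head[cx, cy] = -1
    for i in range(n):
        cx = int(x[i, 0] / cell)
        cy = int(x[i, 1] / cell)
        if cx < 0:
            cx = 0
        elif cx >= ncell:
            cx = ncell - 1
        if cy < 0:
            cy = 0
        elif cy >= ncell:
            cy = ncell - 1
        nxt[i] = head[cx, cy]
        head[cx, cy] = i


@njit(cache=True, inline="always")
def _overlap_angle(i, j):
    h = math.sin(i * 12.9898 + j * 78.233) * 43758.5453123
    return 2.0 * math.pi * (h - math.floor(h))


@njit(cache=True)
def _pair_interact(
    i, j, x, e, d_soc, a_soc, beta_soc, gamma, F,
    radius, s, dwell_steps, unique_pairs, cumulative,
    streak, last, registered, counts, events, n_events,
):
    """Social force and dwell bookkeeping for one pair, one distance eval."""
    dx = x[i, 0] - x[j, 0]
    dy = x[i, 1] - x[j, 1]
    d2 = dx * dx + dy * dy
    # cheap squared-distance rejection before the sqrt
    if d2 >= radius * radius and d2 >= d_soc[i] * d_soc[i] and d2 >= d_soc[j] * d_soc[j]:
        return n_events
    d = math.sqrt(d2)
    if d < radius:
        a, b = (i, j) if i < j else (j, i)
        # under unique-pair counting a registered pair needs no bookkeeping
        if not (unique_pairs and registered[a, b] == 1):
            if cumulative or last[a, b] == s - 1:
                st = streak[a, b] + 1
            else:
                st = 1
            streak[a, b] = st
            last[a, b] = s
            if st == dwell_steps and (not unique_pairs or registered[a, b] == 0):
                registered[a, b] = 1
                counts[a, b] += 1
                if n_events < events.shape[0]:
                    events[n_events, 0] = a
                    events[n_events, 1] = b
                    events[n_events, 2] = s
                n_events += 1
    if d >= d_soc[i] and d >= d_soc[j]:
        return n_events
    if d < 1e-6:
        if d < d_soc[i]:
            a = _overlap_angle(i, j)
            F[i, 0] += a_soc * math.cos(a)
            F[i, 1] += a_soc * math.sin(a)
        if d < d_soc[j]:
            a = _overlap_angle(j, i)
            F[j, 0] += a_soc * math.cos(a)
            F[j, 1] += a_soc * math.sin(a)
        return n_events
    ex = dx / d  # unit vector j -> i
    ey = dy / d
    if d < d_soc[i]:
        cos_phi = -(e[i, 0] * ex + e[i, 1] * ey)
        w = gamma + (1.0 - gamma) * (1.0 + cos_phi) * 0.5
        mag = a_soc * math.exp((d - d_soc[i]) / beta_soc) * w
        F[i, 0] += mag * ex
        F[i, 1] += mag * ey
    if d < d_soc[j]:
        cos_phi = e[j, 0] * ex + e[j, 1] * ey
        w = gamma + (1.0 - gamma) * (1.0 + cos_phi) * 0.5
        mag = a_soc * math.exp((d - d_soc[j]) / beta_soc) * w
        F[j, 0] -= mag * ex
        F[j, 1] -= mag * ey
    return n_events


@njit(cache=True)
def _run(
    x, v, e, mass, v_d, d_soc, tau,
    a_soc, beta_soc, gamma, a_obs, beta_obs, d_obs,
    side, dt, n_steps, reroute_steps, re_idx, re_ang,
    radius, dwell_steps, unique_pairs, cumulative,
    rec_every, traj,
):
    n = x.shape[0]
    cut = radius
    for i in range(n):
        if d_soc[i] > cut:
            cut = d_soc[i]
    ncell = int(side / cut)
    if ncell < 1:
        ncell = 1
    cell = side / ncell

    head = np.empty((ncell, ncell), np.int64)
    nxt = np.empty(n, np.int64)
    F = np.empty((n, 2))
    streak = np.zeros((n, n), np.int32)
    last = np.full((n, n), -2, np.int32)
    registered = np.zeros((n, n), np.uint8)
    counts = np.zeros((n, n), np.int32)
    cap = n * (n - 1) // 2 + 1000
    events = np.empty((cap, 3), np.int64)
    n_events = 0
    event = 0
    rec = 0
    if rec_every > 0:
        for i in range(n):
            traj[0, i, 0] = x[i, 0]
            traj[0, i, 1] = x[i, 1]
            traj[0, i, 2] = v[i, 0]
            traj[0, i, 3] = v[i, 1]
        rec = 1

    for s in range(1, n_steps + 1):
        if s > 1 and (s - 1) % reroute_steps == 0 and event < re_idx.shape[0]:
            for k in range(re_idx.shape[1]):
                a = re_idx[event, k]
                e[a, 0] = math.cos(re_ang[event, k])
                e[a, 1] = math.sin(re_ang[event, k])
            event += 1

        # self-driven + wall forces
        for i in range(n):
            F[i, 0] = mass[i] * (v_d[i] * e[i, 0] - v[i, 0]) / tau[i]
            F[i, 1] = mass[i] * (v_d[i] * e[i, 1] - v[i, 1]) / tau[i]
            for axis in range(2):
                d_low = x[i, axis]
                if d_low < d_obs:
                    F[i, axis] += a_obs * math.exp((d_low - d_obs) / beta_obs)
                d_high = side - x[i, axis]
                if d_high < d_obs:
                    F[i, axis] -= a_obs * math.exp((d_high - d_obs) / beta_obs)

        # one scan over the cell grid per step: social forces and dwell
        # observations, both on the pre-step positions, each pair once
        _grid_build(x, cell, ncell, head, nxt)
        for cx in range(ncell):
            for cy in range(ncell):
                i = head[cx, cy]
                while i != -1:
                    j = nxt[i]
                    while j != -1:
                        n_events = _pair_interact(
                            i, j, x, e, d_soc, a_soc, beta_soc, gamma, F,
                            radius, s, dwell_steps, unique_pairs, cumulative,
                            streak, last, registered, counts, events, n_events,
                        )
                        j = nxt[j]
                    for k in range(4):
                        if k == 0:
                            ox, oy = 1, -1
                        elif k == 1:
                            ox, oy = 1, 0
                        elif k == 2:
                            ox, oy = 1, 1
                        else:
                            ox, oy = 0, 1
                        ax, ay = cx + ox, cy + oy
                        if 0 <= ax < ncell and 0 <= ay < ncell:
                            j = head[ax, ay]
                            while j != -1:
                                n_events = _pair_interact(
                                    i, j, x, e, d_soc, a_soc, beta_soc, gamma,
                                    F, radius, s, dwell_steps, unique_pairs,
                                    cumulative, streak, last, registered,
                                    counts, events, n_events,
                                )
                                j = nxt[j]
                    i = nxt[i]

        # semi-implicit Euler + boundary rule
        for i in range(n):
            for axis in range(2):
                if not math.isfinite(F[i, axis]):
                    return counts, events, -(s), x, v, e, rec
                v[i, axis] += F[i, axis] / mass[i] * dt
                x[i, axis] += v[i, axis] * dt
            if x[i, 0] <= 0.0:
                e[i, 0] = abs(e[i, 0])
                v[i, 0] = abs(v[i, 0])
                x[i, 0] = 0.0
            elif x[i, 0] >= side:
                e[i, 0] = -abs(e[i, 0])
                v[i, 0] = -abs(v[i, 0])
                x[i, 0] = side
            if x[i, 1] <= 0.0:
                e[i, 1] = abs(e[i, 1])
                v[i, 1] = abs(v[i, 1])
                x[i, 1] = 0.0
            elif x[i, 1] >= side:
                e[i, 1] = -abs(e[i, 1])
                v[i, 1] = -abs(v[i, 1])
                x[i, 1] = side

        if rec_every > 0 and s % rec_every == 0:
            for i in range(n):
                traj[rec, i, 0] = x[i, 0]
                traj[rec, i, 1] = x[i, 1]
                traj[rec, i, 2] = v[i, 0]
                traj[rec, i, 3] = v[i, 1]
            rec += 1

    return counts, events, n_events, x, v, e, rec


def run_compiled(
    profiles,
    x0,
    e0,
    force,
    contact_def: ContactDefinition,
    domain,
    dt,
    n_steps,
    reroute_steps,
    re_idx,
    re_ang,
    record_every,
    duration,
):
    """Drive the compiled kernel and package a SimulationResult."""
    from .dynamics import SimulationError, SimulationResult, SimulationState

    n = len(profiles)
    mass = np.array([p.mass for p in profiles])
    v_d = np.array([p.desired_speed for p in profiles])
    d_soc = np.array([p.desired_distance for p in profiles])
    tau = np.array([p.relaxation_time for p in profiles])
    x = np.array(x0, dtype=np.float64)
    v = np.zeros((n, 2))
    e = np.array(e0, dtype=np.float64)
    dwell_steps = int(math.ceil((contact_def.dwell - _DWELL_EPS) / dt)) if contact_def.dwell > 0 else 1
    n_frames = n_steps // record_every + 1 if record_every else 1
    traj = np.zeros((n_frames if record_every else 0, n, 4))

    counts, events, n_events, x, v, e, rec = _run(
        x, v, e, mass, v_d, d_soc, tau,
        force.a_soc, force.beta_soc, force.gamma,
        force.a_obs, force.beta_obs, force.d_obs,
        domain.side, dt, n_steps, reroute_steps,
        np.ascontiguousarray(re_idx, dtype=np.int64),
        np.ascontiguousarray(re_ang, dtype=np.float64),
        contact_def.radius, dwell_steps,
        contact_def.unique_pairs, contact_def.cumulative,
        record_every, traj,
    )
    if n_events < 0:
        raise SimulationError(f"non-finite force at step {-n_events}")
    if n_events > events.shape[0]:
        raise SimulationError("contact event buffer overflow")
    order = np.argsort(events[:n_events, 2], kind="stable")
    contact_pairs = [
        (int(events[k, 0]), int(events[k, 1])) for k in order
    ]
    state = SimulationState(
        t=n_steps * dt, positions=x, velocities=v, desired_dirs=e, profiles=list(profiles)
    )
    times = None
    if record_every:
        times = np.arange(rec) * record_every * dt
    return SimulationResult(
        profiles=list(profiles),
        contact_pairs=contact_pairs,
        state=state,
        n_steps=n_steps,
        dt=dt,
        duration=duration,
        trajectory=traj[:rec] if record_every else None,
        trajectory_times=times,
    )
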