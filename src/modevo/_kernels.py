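"""Numba-compiled inner loops for lifetime simulation.

All kernels operate on the padded dense phenotype arrays built by
:class:`modevo.network.NetworkState`:

- ``w_act``  (L-1, W, W): weights of activity-carrying connections
  (source neuron is non-modulatory); ``w_act[l, t, s]`` is the weight
  from neuron ``s`` of layer ``l`` to neuron ``t`` of layer ``l+1``.
  These are the plastic weights and are mutated in place by learning.
- ``w_mod``  (L-1, W, W): weights of modulatory connections (source is
  a modulatory neuron).  Never change during a lifetime.
- ``plastic`` (L-1, W, W) bool: True where an activity connection exists.
- ``bias``   (L, W): per-neuron biases (layer 0 unused).
- ``sizes``  (L,) int64: neurons per layer.
- ``a``, ``m`` (L, W): activation and modulation scratch buffers.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def forward(w_act, w_mod, bias, sizes, lam, neuromod_on, a, m):
    """One full feed-forward pass; refreshes activations and modulation.

    Returns the output neuron's activation (layer L-1, index 0).
    """
    n_layers = sizes.shape[0]
    for l in range(1, n_layers):
        for i in range(sizes[l]):
            s = bias[l, i]
            sm = 0.0
            for j in range(sizes[l - 1]):
                s += w_act[l - 1, i, j] * a[l - 1, j]
                sm += w_mod[l - 1, i, j] * a[l - 1, j]
            a[l, i] = math.tanh(lam * s)
            if neuromod_on:
                m[l, i] = math.tanh(lam * sm)
            else:
                m[l, i] = 1.0
    return a[n_layers - 1, 0]


@njit(cache=True)
def hebbian_update(w_act, plastic, sizes, a, m, eta):
    """Modulated Hebbian step on every plastic connection, with clamping."""
    n_layers = sizes.shape[0]
    for l in range(n_layers - 1):
        for i in range(sizes[l + 1]):
            g = eta * m[l + 1, i] * a[l + 1, i]
            if g == 0.0:
                continue
            for j in range(sizes[l]):
                if plastic[l, i, j]:
                    w = w_act[l, i, j] + g * a[l, j]
                    if w > 1.0:
                        w = 1.0
                    elif w < -1.0:
                        w = -1.0
                    w_act[l, i, j] = w


@njit(cache=True)
def run_item(w_act, w_mod, bias, plastic, sizes, lam, eta, neuromod_on, learn,
             a, m, input_idx, nutritious, reward_idx, punish_idx):
    """One food-item encounter: decision pass, then outcome pass.

    Plasticity is applied after both passes when ``learn`` is on.
    Returns True if the item was eaten.
    """
    for j in range(sizes[0]):
        a[0, j] = 0.0
    a[0, input_idx] = 1.0
    out = forward(w_act, w_mod, bias, sizes, lam, neuromod_on, a, m)
    ate = out > 0.0
    if learn:
        hebbian_update(w_act, plastic, sizes, a, m, eta)
    if ate:
        if nutritious:
            a[0, reward_idx] = 1.0
        else:
            a[0, punish_idx] = 1.0
    forward(w_act, w_mod, bias, sizes, lam, neuromod_on, a, m)
    if learn:
        hebbian_update(w_act, plastic, sizes, a, m, eta)
    return ate


@njit(cache=True)
def run_day(w_act, w_mod, bias, plastic, sizes, lam, eta, neuromod_on, learn,
            a, m, items, season, edibility, items_per_season,
            reward_idx, punish_idx, ate_out):
    """Present one day's items in order; returns the day score in [0, 1]."""
    n_nutritious = 0
    for k in range(edibility.shape[1]):
        if edibility[season, k]:
            n_nutritious += 1
    eaten_food = 0
    eaten_poison = 0
    for k in range(items.shape[0]):
        item = items[k]
        nutritious = edibility[season, item]
        ate = run_item(w_act, w_mod, bias, plastic, sizes, lam, eta,
                       neuromod_on, learn, a, m,
                       season * items_per_season + item, nutritious,
                       reward_idx, punish_idx)
        ate_out[k] = ate
        if ate:
            if nutritious:
                eaten_food += 1
            else:
                eaten_poison += 1
    return 0.5 + (eaten_food - eaten_poison) / (2.0 * n_nutritious)


@njit(cache=True)
def run_lifetime(w_act, w_mod, bias, plastic, sizes, lam, eta, neuromod_on,
                 learn, a, m, day_orders, day_seasons, edibility,
                 items_per_season, reward_idx, punish_idx,
                 reset_days, reset_values, choices_out, day_scores_out):
    """Simulate a full lifetime (all days of all seasons).

    ``reset_days`` lists day indices at which plastic weights are
    overwritten with the corresponding slice of ``reset_values`` (the
    forced-forgetting ablation); pass empty arrays to disable.
    """
    n_days = day_orders.shape[0]
    n_items = day_orders.shape[1]
    for d in range(n_days):
        for r in range(reset_days.shape[0]):
            if reset_days[r] == d:
                for l in range(w_act.shape[0]):
                    for i in range(w_act.shape[1]):
                        for j in range(w_act.shape[2]):
                            if plastic[l, i, j]:
                                w_act[l, i, j] = reset_values[r, l, i, j]
        score = run_day(w_act, w_mod, bias, plastic, sizes, lam, eta,
                        neuromod_on, learn, a, m, day_orders[d],
                        day_seasons[d], edibility, items_per_season,
                        reward_idx, punish_idx,
                        choices_out[d * n_items:(d + 1) * n_items])
        day_scores_out[d] = score
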