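"""Numba kernels shared by the op-level API and the fast participant loop.

All model arithmetic lives here, in one place, so the cycle-level semantics
of the object API (:mod:`pepsim.network_core`, :mod:`pepsim.episodic_store`)
and of the vectorized per-participant driver are identical by construction.

Model definition (see docs/methods.md for the full account)
-----------------------------------------------------------
Activations live in [0, 1] with rest at 0.  A node with positive
deterministic drive moves toward it each cycle with multiplicative
Gaussian drive noise; an undriven node decays multiplicatively
(``decay_node``, goals ``decay_goal``).  Input nodes integrate at
``change_toward_stimulus``; decision, response and goal nodes are slow
integrators (rate scaled by ``central_rate_scale``).  Decision drive is
gated by sensitivity (``preparation_base + weight_goal_decision x goal``);
responses are competing leaky accumulators of their retrieval share,
active only once a decision is made; goal nodes compete laterally.

Episodic retrieval: each episode is a sparse weight row over the 20 nodes
with a decayable strength.  Similarity is the search-weighted dot product
of probe activations with the episode weights over destination-specific
probe layers: goals are retrieved by cue and goal (self-retrieval carries
goal inertia) with a linear similarity->activation mapping; decisions by
cue and target only; responses by cue, target (reduced weight), decisions
and responses (own term excluded), both with the cubic exemplar-model
mapping and multiplicative amplification by the active bound goal.
Within each layer the summed positive drive is normalized to a bounded
budget (``raw / (1 + total)``): retrieval is proportional/competitive.

Memory search is staged: full cue->goal search until a goal has been above
``threshold_goal`` for ``goal_confirm_cycles`` consecutive cycles, then
cue search is damped by ``search_goal_after_selected`` while the
target-based searches come up to full strength; a decision is made when
the digit's decision on the held goal's dimension crosses
``decision_threshold`` (stimulus search then scales by
``search_stimulus_after_decision``); post trial all searches are damped.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .layout import (
    DECISION_GOAL,
    DIGIT_DECISIONS,
    HARDWIRED_DIGIT_DECISION,
    N_NODES,
)
from .params import (
    P_CHANGE,
    P_CUE_LEAD,
    P_DEADLINE,
    P_DECAY_EPISODE,
    P_DECAY_GOAL,
    P_DECAY_NODE,
    P_DECISION_THRESHOLD,
    P_GOAL_COMPETITION,
    P_GOAL_CONFIRM,
    P_RATE_SCALE,
    P_SR_WEIGHT,
    P_WEAKEN_SAT,
    P_GOAL_SEARCH_WEIGHT,
    P_HARDWIRED_WEIGHT,
    P_LOSS_EPISODE,
    P_NEGATIVE_WEIGHTS,
    P_NOISE_DECISION,
    P_NOISE_GOAL,
    P_NOISE_INPUT,
    P_NOISE_RESPONSE,
    P_POST_TRIAL_DAMP,
    P_PREP_BASE,
    P_RCI,
    P_RESPONSE_CODING,
    P_RESP_GAIN,
    P_RESPONSE_COMPETITION,
    P_RESPONSE_THRESHOLD,
    P_RESTORE_ERRORS_ONLY,
    P_RESTORE_INSTRUCTION,
    P_RETRIEVAL_REFRESH,
    P_SEARCH_GOAL_AFTER,
    P_SEARCH_STIM_AFTER,
    P_STRENGTH_CUE,
    P_STRENGTH_DECISION,
    P_STRENGTH_GOAL,
    P_STRENGTH_RESPONSE,
    P_STRENGTH_TARGET,
    P_THRESHOLD_GOAL,
    P_WEIGHT_GOAL_DECISION,
)

_HARD = HARDWIRED_DIGIT_DECISION
_DEC_GOAL = DECISION_GOAL
_DIG_DEC = DIGIT_DECISIONS


@njit(cache=False)
def probe_weights(pv, goal_selected, decision_made, post_trial):
    """Per-node memory search weights for the current trial stage."""
    cs = pv[P_STRENGTH_CUE]
    ts = pv[P_STRENGTH_TARGET]
    ds = pv[P_STRENGTH_DECISION]
    rs = pv[P_STRENGTH_RESPONSE]
    gw = 1.0
    damp = pv[P_SEARCH_GOAL_AFTER]
    if goal_selected:
        cs *= damp
    else:
        ts *= damp
        ds *= damp
    if decision_made:
        ts *= pv[P_SEARCH_STIM_AFTER]
    else:
        rs *= damp
    if post_trial:
        pd = pv[P_POST_TRIAL_DAMP]
        cs *= pd
        ts *= pd
        ds *= pd
        rs *= pd
        gw *= pd
    pw = np.empty(N_NODES)
    for n in range(4):
        pw[n] = cs
    for n in range(4, 12):
        pw[n] = ts
    for n in range(12, 16):
        pw[n] = ds
    for n in range(16, 18):
        pw[n] = rs
    for n in range(18, 20):
        pw[n] = gw
    return pw


@njit(cache=False)
def episode_similarities(a, W, S, n_epi, pw):
    """Rectified search-weighted dot-product similarity of each episode."""
    sims = np.zeros(n_epi)
    for e in range(n_epi):
        sim = 0.0
        for k in range(N_NODES):
            w = W[e, k]
            if w != 0.0:
                sim += pw[k] * a[k] * w
        if sim > 0.0:
            sims[e] = sim
    return sims


# Which probe layers participate in the memory search that retrieves each
# destination layer (rows: destination; columns: source; layer order
# cues, digits, decisions, responses, goals).  Goals are retrieved on the
# basis of the cue (and of themselves: a selected goal re-retrieves itself
# through the episodes that bind it, which maintains the task goal across
# the trial and carries inertia into the next one).  Decisions are
# retrieved on the basis of the cue and the target -- never of other
# decisions, so there is no decision self-priming loop.  Responses are
# retrieved by everything (stimulus-response, decision-response and
# response-repetition bindings); an episode's drive to a response excludes
# that response's own probe term (no self-connections).
_LAYER_BOUNDS = (0, 4, 12, 16, 18, 20)


@njit(cache=False)
def compute_retrieval(a, W, S, n_epi, pw, goal_gate, pw_sr):
    """Normalized per-node retrieval drive from the episode store.

    Each episode's drive to a bound node is proportional to the episode's
    search-weighted similarity over the probe layers relevant for that
    node's layer, mapped through the layer's similarity->activation rule
    (linear for goals, cubic with goal gating for decisions/responses),
    times the episode's strength.  Within each layer the summed positive
    raw drive is squashed as ``raw / (1 + total)`` so that competing
    options share a bounded budget (proportional retrieval).
    """
    raw = np.zeros(N_NODES)
    part = np.zeros(5)
    sr_w = pw_sr
    for e in range(n_epi):
        for l in range(5):
            part[l] = 0.0
        for k in range(N_NODES):
            w = W[e, k]
            if w != 0.0:
                if k < 4:
                    part[0] += pw[k] * a[k] * w
                elif k < 12:
                    part[1] += pw[k] * a[k] * w
                elif k < 16:
                    part[2] += pw[k] * a[k] * w
                elif k < 18:
                    part[3] += pw[k] * a[k] * w
                else:
                    part[4] += pw[k] * a[k] * w
        s_e = S[e]
        if s_e < 1e-3:
            continue  # fully eroded episodes contribute nothing measurable
        for k in range(N_NODES):
            w = W[e, k]
            if w == 0.0:
                continue
            if k < 4:
                dest = 0
            elif k < 12:
                dest = 1
            elif k < 16:
                dest = 2
            elif k < 18:
                dest = 3
            else:
                dest = 4
            if dest == 2:
                sim = part[0] + part[1]
            elif dest == 3:
                sim = part[0] + sr_w * part[1] + part[2] + part[3]
                # leave-one-out: a response does not retrieve itself
                sim -= pw[k] * a[k] * w
            elif dest == 4:
                sim = part[0] + part[4]
            else:
                sim = 0.0
            if sim > 0.0:
                if dest == 4:
                    # goal retrieval is linear: weak residual activation of
                    # the previous task goal re-retrieves itself through the
                    # many episodes that bind it (recurrent retrieval), the
                    # carrier of goal inertia
                    act = sim * s_e
                else:
                    # cubic similarity->activation mapping for item layers:
                    # episodes matching on several features dominate partial
                    # matches, keeping retrieval stimulus-driven even with
                    # hundreds of stored episodes (the classic
                    # exemplar-model nonlinearity)
                    act = sim * sim * sim * s_e
                    if dest == 2 or dest == 3:
                        # the active goal gates item retrieval: episodes
                        # bound to the current task goal are amplified,
                        # goal-only matches contribute nothing by themselves
                        act *= 1.0 + goal_gate * part[4]
                raw[k] += act * w
    out = np.zeros(N_NODES)
    for b in range(5):
        lo = _LAYER_BOUNDS[b]
        hi = _LAYER_BOUNDS[b + 1]
        total = 0.0
        for n in range(lo, hi):
            if raw[n] > 0.0:
                total += raw[n]
        scale = 1.0 / (1.0 + total)
        for n in range(lo, hi):
            out[n] = raw[n] * scale
    return out


@njit(cache=False)
def step_nodes(a, retrieval, ext, pv, eps, target_on, decision_made, held_goal):
    """One processing cycle: update all activations in place.

    ``retrieval`` is the (possibly cached) normalized retrieval drive,
    ``ext`` the external stimulus drive, ``eps`` a vector of 20 standard
    normal draws scaled by the layer noise magnitudes.  The response-coding
    gain is damped until a decision has been made (staged search), so
    memory can pre-activate responses during preparation without racing
    them to threshold.
    """
    change = pv[P_CHANGE]
    decay_node = pv[P_DECAY_NODE]
    decay_goal = pv[P_DECAY_GOAL]

    # input nodes (cues 0-3, digits 4-11)
    for n in range(12):
        det = ext[n] + retrieval[n]
        if det > 0.0:
            sig = det * (1.0 + eps[n] * pv[P_NOISE_INPUT])
            a[n] += change * (sig - a[n])
        else:
            a[n] *= 1.0 - decay_node
        if a[n] < 0.0:
            a[n] = 0.0
        elif a[n] > 1.0:
            a[n] = 1.0

    # decision nodes (12-15): hardwired digit drive + retrieval, with
    # goal-scaled sensitivity
    hw = pv[P_HARDWIRED_WEIGHT]
    prep = pv[P_PREP_BASE]
    wgd = pv[P_WEIGHT_GOAL_DECISION]
    # decision-directed retrieval is damped until the target is up:
    # decisions are searched for "on the basis of the target"
    dgain = 1.0 if target_on else pv[P_SEARCH_GOAL_AFTER]
    for j in range(4):
        n = 12 + j
        hard = 0.0
        for d in range(8):
            if _HARD[j, d] != 0.0:
                hard += a[4 + d]
        sens = prep + wgd * a[18 + _DEC_GOAL[j]]
        det = sens * (hw * hard + dgain * retrieval[n])
        if det > 0.0:
            sig = det * (1.0 + eps[n] * pv[P_NOISE_DECISION])
            a[n] += change * pv[P_RATE_SCALE] * (sig - a[n])
        else:
            a[n] *= 1.0 - decay_node
        if a[n] < 0.0:
            a[n] = 0.0
        elif a[n] > 1.0:
            a[n] = 1.0

    # response nodes (16-17): competing leaky accumulators driven by their
    # retrieval share; mutual inhibition makes closely matched retrieval
    # (partial repetitions, incongruent stimuli) settle slowly
    coding = pv[P_RESPONSE_CODING] * pv[P_RESP_GAIN]
    if not decision_made:
        coding = 0.0  # responses accumulate only once a decision is made
    rcomp = pv[P_RESPONSE_COMPETITION]
    det16 = coding * retrieval[16] - rcomp * a[17]
    det17 = coding * retrieval[17] - rcomp * a[16]
    for n in range(16, 18):
        det = det16 if n == 16 else det17
        if det > 0.0:
            sig = det * (1.0 + eps[n] * pv[P_NOISE_RESPONSE])
            a[n] += change * pv[P_RATE_SCALE] * (sig - a[n])
        else:
            a[n] *= 1.0 - decay_node
        if a[n] < 0.0:
            a[n] = 0.0
        elif a[n] > 1.0:
            a[n] = 1.0

    # goal nodes (18-19) with lateral competition
    sg = pv[P_STRENGTH_GOAL]
    comp = pv[P_GOAL_COMPETITION]
    grate = change * pv[P_RATE_SCALE]
    det0 = sg * retrieval[18] - comp * a[19]
    det1 = sg * retrieval[19] - comp * a[18]
    for g in range(2):
        n = 18 + g
        det = det0 if g == 0 else det1
        if det > 0.0:
            a[n] += grate * (det * (1.0 + eps[n] * pv[P_NOISE_GOAL]) - a[n])
        else:
            a[n] *= 1.0 - decay_goal
    for n in range(18, 20):
        if a[n] < 0.0:
            a[n] = 0.0
        elif a[n] > 1.0:
            a[n] = 1.0


@njit(cache=False)
def weaken_episodes(W, S, n_epi, a, pw, loss, sat):
    """Retrieval-induced weakening, proportional to current similarity."""
    if loss <= 0.0:
        return
    for e in range(n_epi):
        sim = 0.0
        for k in range(18):  # item features only: goal bindings alone do
            w = W[e, k]      # not make an episode a retrieval competitor
            if w != 0.0:
                sim += pw[k] * a[k] * w
        if sim > 0.0:
            # weakening saturates for very similar episodes (at ``sat``
            # times the nominal loss rate), so frequent events erode
            # steadily without the store being wiped outright
            f = 1.0 - loss * sim / (1.0 + sim / sat)
            if f < 0.0:
                f = 0.0
            S[e] *= f


@njit(cache=False)
def decay_episode_strengths(S, n_epi, decay):
    for e in range(n_epi):
        S[e] *= 1.0 - decay


@njit(cache=False)
def restore_instruction_strengths(S, n_instr, restore):
    for e in range(n_instr):
        S[e] += restore * (1.0 - S[e])


@njit(cache=False)
def rci_decay_cycle(a, pv, ablate):
    """One response-cue-interval cycle: pure decay (no stimulus, no search).

    With the goal-inertia ablation on, the two goal activations are set to
    their arithmetic mean on every cycle of the interval.
    """
    dn = pv[P_DECAY_NODE]
    dg = pv[P_DECAY_GOAL]
    for n in range(18):
        a[n] *= 1.0 - dn
    a[18] *= 1.0 - dg
    a[19] *= 1.0 - dg
    if ablate:
        m = 0.5 * (a[18] + a[19])
        a[18] = m
        a[19] = m


@njit(cache=False)
def run_participant_core(
    cue_nodes,      # int64[n_trials]  flat node index of each trial's cue
    digit_nodes,    # int64[n_trials]  flat node index of each trial's digit
    correct_resp,   # int64[n_trials]  correct response index (0 left, 1 right)
    pv,             # packed parameter vector
    ablate,         # goal-inertia ablation flag
    rng,            # np.random.Generator
    W,              # float64[8 + n_trials, 20] episode weights (instructions pre-filled)
    S,              # float64[8 + n_trials] episode strengths (instructions pre-filled)
    n_instr,        # number of pre-filled instruction episodes (8)
    out_resp,       # int64[n_trials]  emitted response (-1 omission)
    out_rt,         # int64[n_trials]  cycles from target onset (-1 omission)
    out_dec,        # int64[n_trials]  most active decision at trial end
    out_goal,       # int64[n_trials]  most active goal at trial end
):
    """Simulate one participant's full trial sequence; returns episode count."""
    n_trials = cue_nodes.shape[0]
    a = np.zeros(N_NODES)
    ext = np.zeros(N_NODES)
    n_epi = n_instr

    cue_lead = int(pv[P_CUE_LEAD])
    deadline = int(pv[P_DEADLINE])
    rci = int(pv[P_RCI])
    refresh = int(pv[P_RETRIEVAL_REFRESH])
    thr_goal = pv[P_THRESHOLD_GOAL]
    thr_dec = pv[P_DECISION_THRESHOLD]
    thr_resp = pv[P_RESPONSE_THRESHOLD]

    retrieval = np.zeros(N_NODES)

    for t in range(n_trials):
        goal_sel = False
        dec_made = False
        held_goal = -1
        goal_confirm = 0
        cue_n = cue_nodes[t]
        dig_n = digit_nodes[t]

        # ---- cue phase -------------------------------------------------
        for n in range(N_NODES):
            ext[n] = 0.0
        ext[cue_n] = 1.0
        need = True
        since = 0
        for c in range(cue_lead):
            if need or since >= refresh:
                pw = probe_weights(pv, goal_sel, dec_made, False)
                retrieval = compute_retrieval(a, W, S, n_epi, pw, pv[P_GOAL_SEARCH_WEIGHT], pv[P_SR_WEIGHT])
                since = 0
                need = False
            eps = rng.standard_normal(N_NODES)
            step_nodes(a, retrieval, ext, pv, eps, False, dec_made, held_goal)
            since += 1
            if not goal_sel:
                if a[18] >= thr_goal or a[19] >= thr_goal:
                    goal_confirm += 1
                else:
                    goal_confirm = 0
                if goal_confirm >= int(pv[P_GOAL_CONFIRM]):
                    goal_sel = True
                    held_goal = 0 if a[18] >= a[19] else 1
                    need = True
            # decisions about the not-yet-presented target cannot be made:
            # the decision latch only operates in the target phase

        # ---- target phase (the cue stays on with the target) ------------
        ext[dig_n] = 1.0
        need = True
        since = 0
        resp = -1
        rt = -1
        latched_dec = -1
        for c in range(deadline):
            if need or since >= (3 if dec_made else refresh):
                pw = probe_weights(pv, goal_sel, dec_made, False)
                retrieval = compute_retrieval(a, W, S, n_epi, pw, pv[P_GOAL_SEARCH_WEIGHT], pv[P_SR_WEIGHT])
                since = 0
                need = False
            eps = rng.standard_normal(N_NODES)
            step_nodes(a, retrieval, ext, pv, eps, True, dec_made, held_goal)
            since += 1
            if not goal_sel:
                if a[18] >= thr_goal or a[19] >= thr_goal:
                    goal_confirm += 1
                else:
                    goal_confirm = 0
                if goal_confirm >= int(pv[P_GOAL_CONFIRM]):
                    goal_sel = True
                    held_goal = 0 if a[18] >= a[19] else 1
                    need = True
            if not dec_made:
                # the decision latch requires target-consistent evidence on
                # the dimension the system is set for: the presented
                # digit's decision belonging to the held goal (either
                # afforded decision if no goal is committed yet)
                d_idx = dig_n - 4
                j0 = _DIG_DEC[d_idx, 0]
                j1 = _DIG_DEC[d_idx, 1]
                if held_goal == 0:
                    cand = j0
                elif held_goal == 1:
                    cand = j1
                else:
                    cand = j0 if a[12 + j0] >= a[12 + j1] else j1
                if a[12 + cand] >= thr_dec:
                    dec_made = True
                    latched_dec = cand
                    need = True
            c0 = a[16] >= thr_resp
            c1 = a[17] >= thr_resp
            if c0 or c1:
                if c0 and c1:
                    resp = 0 if a[16] >= a[17] else 1
                elif c0:
                    resp = 0
                else:
                    resp = 1
                rt = c + 1
                break

        # ---- trial outcome ----------------------------------------------
        if latched_dec >= 0:
            dec_e = latched_dec
        else:
            dec_e = 0
            best = a[12]
            for j in range(1, 4):
                if a[12 + j] > best:
                    best = a[12 + j]
                    dec_e = j
        goal_e = held_goal if held_goal >= 0 else (0 if a[18] >= a[19] else 1)
        out_resp[t] = resp
        out_rt[t] = rt
        out_dec[t] = dec_e
        out_goal[t] = goal_e

        # ---- encoding, weakening, decay, instruction maintenance --------
        pw = probe_weights(pv, goal_sel, dec_made, False)
        weaken_episodes(W, S, n_epi, a, pw, pv[P_LOSS_EPISODE], pv[P_WEAKEN_SAT])
        W[n_epi, cue_n] = 1.0
        W[n_epi, dig_n] = 1.0
        W[n_epi, 12 + dec_e] = 1.0
        W[n_epi, 18 + goal_e] = 1.0
        if resp >= 0:
            W[n_epi, 16 + resp] = 1.0
            W[n_epi, 16 + (1 - resp)] = pv[P_NEGATIVE_WEIGHTS]
        S[n_epi] = 1.0
        n_epi += 1
        decay_episode_strengths(S, n_epi, pv[P_DECAY_EPISODE])
        err = resp >= 0 and resp != correct_resp[t]
        if pv[P_RESTORE_ERRORS_ONLY] == 0.0 or err or resp < 0:
            restore_instruction_strengths(S, n_instr, pv[P_RESTORE_INSTRUCTION])

        # ---- response-cue interval --------------------------------------
        for c in range(rci):
            rci_decay_cycle(a, pv, ablate)

    return n_epi
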