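"""Compiled closed-loop session engine.

One call of :func:`run_session_kernel` simulates a full virtual-day session
(default 900 s at dt = 0.01 s): salience generation -> selection network ->
action subsystems -> arena kinematics -> schedule/flash -> prediction update
-> phasic dopamine -> gated BCM plasticity.  All randomness (input noise,
explore-salience draws, wander headings, VI intervals) comes from one stream
seeded per session, which makes sessions bitwise reproducible.

The kernel mutates the carried-over state arrays in place (network weights,
<y^2> trackers, prediction/salience values) and appends one row per completed
block interaction to the event log (see ``EV_*`` column constants).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from actdisc import network as nw
from actdisc.arena import (clamp_position, diff_drive, explore_command,
                           interact_fsm_step, near_obstacle, rect_distance,
                           visible, wrap_angle)
from actdisc.config import RunConfig
from actdisc.dopamine import snc_input, snc_output, triangular_pulse
from actdisc.plasticity import _c_bcm_scalar, weight_update

# --- packed scalar-parameter indices ---------------------------------------
(P_DT, P_TAU, P_PHI, P_LAM, P_NOISE, P_SESSION_LEN,
 P_SIZE, P_AGENT_R, P_CONTACT, P_FOV_HALF, P_FOV_RANGE, P_FLASH_DUR,
 P_V_EXPLORE, P_V_APPROACH, P_V_BACKOFF, P_V_REAPPROACH, P_V_MAX,
 P_TURN_GAIN, P_BACKOFF_T, P_STOP_T, P_AVOID, P_HEADING_REDRAW, P_AXLE,
 P_EXPL_LOW, P_EXPL_HIGH, P_EXPL_REDRAW,
 P_K, P_FIRST_FLASH, P_GAMMA_B,
 P_A_PLUS, P_A_MINUS, P_PULSE_W, P_TAU_SNC, P_D_REST,
 P_ETA, P_C_GAIN, P_TAU_RATIO, P_YSQ_TAU, P_W_MIN, P_W_MAX, P_WINDOW,
 P_AP_D1_HI, P_AM_D1_HI, P_AP_D1_LO, P_AM_D1_LO,
 P_AP_D2_HI, P_AM_D2_HI, P_AP_D2_LO, P_AM_D2_LO,
 P_VI_MEAN, P_BLOCK_HALF, P_BLOCK_DEPTH, P_TONIC_PLAST,
 N_PARAMS) = range(54)

# --- prediction/salience state vector indices ------------------------------
PS_Y_LATENT, PS_SEEN_FIRST, PS_SINT_RED, PS_SINT_WHITE, N_PS = range(5)

# --- event-log columns ------------------------------------------------------
(EV_T, EV_BLOCK, EV_FLASH, EV_YSTAR_PRE, EV_Y_POST, EV_SNOV, EV_SINT,
 EV_D_MAX, EV_D_MIN, EV_W_MOT_D1, EV_W_MOT_D2, EV_W_SEN_D1, EV_W_SEN_D2,
 EV_STOT_RED, N_EV_COLS) = range(15)

EVENT_CAP = 4000

CH_EXPLORE, CH_RED, CH_WHITE = 0, 1, 2


def pack_params(config: RunConfig) -> np.ndarray:
    """Flatten the validated config into the kernel's scalar-parameter array."""
    c = config
    p = np.zeros(N_PARAMS)
    p[P_DT] = c.network.dt
    p[P_TAU] = c.network.tau
    p[P_PHI] = c.network.phi
    p[P_LAM] = c.network.lam
    p[P_NOISE] = c.network.noise_sigma
    p[P_SESSION_LEN] = c.protocol.session_length
    p[P_SIZE] = c.arena.size
    p[P_AGENT_R] = c.arena.agent_radius
    p[P_CONTACT] = c.arena.contact_dist
    p[P_FOV_HALF] = math.radians(c.arena.fov_half_angle_deg)
    p[P_FOV_RANGE] = c.arena.fov_range
    p[P_FLASH_DUR] = c.arena.flash_duration
    p[P_V_EXPLORE] = c.arena.speed_explore
    p[P_V_APPROACH] = c.arena.speed_approach
    p[P_V_BACKOFF] = c.arena.speed_backoff
    p[P_V_REAPPROACH] = c.arena.speed_reapproach
    p[P_V_MAX] = c.arena.speed_max
    p[P_TURN_GAIN] = c.arena.turn_gain
    p[P_BACKOFF_T] = c.arena.backoff_time
    p[P_STOP_T] = c.arena.stop_time
    p[P_AVOID] = c.arena.avoid_dist
    p[P_HEADING_REDRAW] = c.arena.explore_heading_redraw
    p[P_AXLE] = c.arena.axle_length
    p[P_EXPL_LOW] = c.prediction.explore_low
    p[P_EXPL_HIGH] = c.prediction.explore_high
    p[P_EXPL_REDRAW] = c.prediction.explore_redraw
    p[P_K] = c.prediction.k
    p[P_FIRST_FLASH] = c.prediction.first_flash_value
    p[P_GAMMA_B] = c.prediction.gamma_b
    p[P_A_PLUS] = c.dopamine.a_plus
    p[P_A_MINUS] = c.dopamine.a_minus
    p[P_PULSE_W] = c.dopamine.pulse_width
    p[P_TAU_SNC] = c.dopamine.tau_snc
    p[P_D_REST] = c.dopamine.rest
    p[P_ETA] = c.plasticity.eta
    p[P_C_GAIN] = c.plasticity.c_gain
    p[P_TAU_RATIO] = c.plasticity.tau_ratio
    p[P_YSQ_TAU] = c.plasticity.ysq_tau
    p[P_W_MIN] = c.plasticity.w_min
    p[P_W_MAX] = c.plasticity.w_max
    p[P_WINDOW] = c.plasticity.window
    p[P_AP_D1_HI] = c.plasticity.a_plus_d1_hi
    p[P_AM_D1_HI] = c.plasticity.a_minus_d1_hi
    p[P_AP_D1_LO] = c.plasticity.a_plus_d1_lo
    p[P_AM_D1_LO] = c.plasticity.a_minus_d1_lo
    p[P_AP_D2_HI] = c.plasticity.a_plus_d2_hi
    p[P_AM_D2_HI] = c.plasticity.a_minus_d2_hi
    p[P_AP_D2_LO] = c.plasticity.a_plus_d2_lo
    p[P_AM_D2_LO] = c.plasticity.a_minus_d2_lo
    p[P_VI_MEAN] = c.protocol.vi_mean
    p[P_BLOCK_HALF] = c.arena.block_half_width
    p[P_BLOCK_DEPTH] = c.arena.block_depth
    p[P_TONIC_PLAST] = 1.0 if c.plasticity.tonic_plasticity else 0.0
    return p


@njit
def run_session_kernel(p, gains, eps, a, w_mot, w_sen, ysq, ps,
                       seed, rc_phase, pda, schedule_fr1, out_ev):
    """Simulate one session; returns the number of logged interactions.

    Mutates: network activations ``a``, weights ``w_mot``/``w_sen``, the
    <y^2> tracker ``ysq``, and the prediction/salience vector ``ps``.
    """
    np.random.seed(seed)
    dt = p[P_DT]
    n_steps = int(round(p[P_SESSION_LEN] / dt))
    size = p[P_SIZE]

    # block rectangles (red against the far wall, white opposite)
    rects = np.empty((2, 4))
    rects[0, 0] = size / 2 - p[P_BLOCK_HALF]
    rects[0, 1] = size - p[P_BLOCK_DEPTH]
    rects[0, 2] = size / 2 + p[P_BLOCK_HALF]
    rects[0, 3] = size
    rects[1, 0] = size / 2 - p[P_BLOCK_HALF]
    rects[1, 1] = 0.0
    rects[1, 2] = size / 2 + p[P_BLOCK_HALF]
    rects[1, 3] = p[P_BLOCK_DEPTH]
    red_cx = 0.5 * (rects[0, 0] + rects[0, 2])
    red_cy = 0.5 * (rects[0, 1] + rects[0, 3])
    white_cx = 0.5 * (rects[1, 0] + rects[1, 2])
    white_cy = 0.5 * (rects[1, 1] + rects[1, 3])

    # agent starts at the arena centre with a random heading
    x = 0.5 * size
    y = 0.5 * size
    th = np.random.uniform(-math.pi, math.pi)
    psi = np.random.uniform(-math.pi, math.pi)

    stage_r, t_stage_r = 0, 0.0
    stage_w, t_stage_w = 0, 0.0
    flash_timer = 0.0

    s_explore = np.random.uniform(p[P_EXPL_LOW], p[P_EXPL_HIGH])
    t_expl_redraw = p[P_EXPL_REDRAW]
    t_heading_redraw = p[P_HEADING_REDRAW]

    # VI schedule (availability timer runs within the session)
    vi_armed = False
    vi_next = np.random.exponential(p[P_VI_MEAN])

    # phasic dopamine state
    a_snc = 0.0
    event_t = -1.0e9
    amp_sc = 0.0
    amp_cancel = 0.0
    ysq_froz_d1 = 0.0
    ysq_froz_d2 = 0.0
    ev_x_mot = 0.0
    ev_x_sen = 0.0
    ev_y_d1 = 0.0
    ev_y_d2 = 0.0
    open_row = -1
    flash_seen = False      # flash delivered at the bump of this sequence
    y_star_flash = 0.0      # prediction read out when that flash arrived
    cur_d_max = p[P_D_REST]
    cur_d_min = p[P_D_REST]

    sal = np.zeros(3)
    noise = np.zeros(3)
    n_ev = 0

    for i in range(n_steps):
        t = i * dt

        if flash_timer > 0.0:
            flash_timer -= dt
        if not vi_armed and t >= vi_next:
            vi_armed = True

        # --- perception and saliences -----------------------------------
        red_vis = visible(x, y, th, red_cx, red_cy, p[P_FOV_HALF],
                          p[P_FOV_RANGE])
        white_vis = visible(x, y, th, white_cx, white_cy, p[P_FOV_HALF],
                            p[P_FOV_RANGE])

        if t >= t_expl_redraw:
            s_explore = np.random.uniform(p[P_EXPL_LOW], p[P_EXPL_HIGH])
            t_expl_redraw += p[P_EXPL_REDRAW]

        s_nov_red = 0.5 - abs(ps[PS_Y_LATENT] - 0.5)
        s_tot_red = ps[PS_SINT_RED] + s_nov_red
        sal[CH_EXPLORE] = s_explore
        sal[CH_RED] = s_tot_red if red_vis else 0.0
        sal[CH_WHITE] = ps[PS_SINT_WHITE] if white_vis else 0.0

        sigma = p[P_NOISE]
        if sigma > 0.0:
            noise[0] = np.random.normal(0.0, sigma)
            noise[1] = np.random.normal(0.0, sigma)
            noise[2] = np.random.normal(0.0, sigma)

        # --- selection network ------------------------------------------
        nw.step_kernel(a, sal, noise, w_mot, w_sen, p[P_LAM], eps, gains,
                       dt, p[P_TAU])
        yout = nw.output_rates(a, eps)
        sel_explore = yout[nw.BS, CH_EXPLORE] > p[P_PHI]
        sel_red = yout[nw.BS, CH_RED] > p[P_PHI]
        sel_white = yout[nw.BS, CH_WHITE] > p[P_PHI]

        # --- action subsystems ------------------------------------------
        zl_sum = 0.0
        zr_sum = 0.0
        n_sel = 0
        bump_red = False
        complete_red = False
        complete_white = False

        if t >= t_heading_redraw:
            psi = np.random.uniform(-math.pi, math.pi)
            t_heading_redraw += p[P_HEADING_REDRAW]
        if sel_explore:
            if near_obstacle(x, y, size, rects, p[P_AVOID]):
                psi = math.atan2(0.5 * size - y, 0.5 * size - x) + \
                    np.random.uniform(-0.5, 0.5)
            zl, zr = explore_command(psi, x, y, th, p[P_V_EXPLORE],
                                     p[P_V_MAX], p[P_TURN_GAIN])
            zl_sum += zl
            zr_sum += zr
            n_sel += 1

        if sel_red:
            zl, zr, stage_r, t_stage_r, bump, complete = interact_fsm_step(
                stage_r, t_stage_r, x, y, th, rects[0], p[P_AGENT_R],
                p[P_CONTACT], p[P_V_APPROACH], p[P_V_BACKOFF],
                p[P_V_REAPPROACH], p[P_V_MAX], p[P_TURN_GAIN],
                p[P_BACKOFF_T], p[P_STOP_T], dt)
            zl_sum += zl
            zr_sum += zr
            n_sel += 1
            bump_red = bump
            complete_red = complete
        else:
            stage_r, t_stage_r = 0, 0.0
            # interruption aborts the response, but a flash already delivered
            # at the bump has been seen (prediction/dopamine already updated)
            flash_seen = False

        if sel_white:
            zl, zr, stage_w, t_stage_w, bump, complete = interact_fsm_step(
                stage_w, t_stage_w, x, y, th, rects[1], p[P_AGENT_R],
                p[P_CONTACT], p[P_V_APPROACH], p[P_V_BACKOFF],
                p[P_V_REAPPROACH], p[P_V_MAX], p[P_TURN_GAIN],
                p[P_BACKOFF_T], p[P_STOP_T], dt)
            zl_sum += zl
            zr_sum += zr
            n_sel += 1
            complete_white = complete
        else:
            stage_w, t_stage_w = 0, 0.0

        # --- motor blending and kinematics ------------------------------
        if n_sel > 0:
            zl = zl_sum / n_sel
            zr = zr_sum / n_sel
        else:
            zl = 0.0
            zr = 0.0
        x, y, th = diff_drive(x, y, th, zl, zr, dt, p[P_AXLE])
        x, y = clamp_position(x, y, p[P_AGENT_R], size, rects)

        # --- schedule gate and flash delivery at the bump ---------------
        # the light (and thus the phasic outcome: prediction update and the
        # dopamine response) is triggered by the bump itself; the completed
        # sequence is what counts as a response
        if bump_red and rc_phase:
            deliver = False
            if schedule_fr1:
                deliver = True
            elif vi_armed:
                deliver = True
                vi_armed = False
                vi_next = t + np.random.exponential(p[P_VI_MEAN])
            if deliver:
                flash_timer = p[P_FLASH_DUR]
                flash_seen = True
                y_star_flash = ps[PS_Y_LATENT]
                if ps[PS_SEEN_FIRST] == 0.0:
                    ps[PS_Y_LATENT] = p[P_FIRST_FLASH]
                    ps[PS_SEEN_FIRST] = 1.0
                else:
                    ps[PS_Y_LATENT] = 1.0 - p[P_K] * (1.0 - ps[PS_Y_LATENT])
                if pda:
                    event_t = t
                    amp_sc = 1.0 - y_star_flash
                    amp_cancel = 0.0
                    ysq_froz_d1 = ysq[0, CH_RED]
                    ysq_froz_d2 = ysq[1, CH_RED]
                    ev_x_mot = yout[nw.MCTX, CH_RED]
                    ev_x_sen = yout[nw.SCTX, CH_RED]
                    ev_y_d1 = yout[nw.D1, CH_RED]
                    ev_y_d2 = yout[nw.D2, CH_RED]
                    cur_d_max = p[P_D_REST]
                    cur_d_min = p[P_D_REST]
                    open_row = -1

        # --- completed interactions -------------------------------------
        if complete_red and n_ev < EVENT_CAP:
            flash = 1.0 if flash_seen else 0.0
            flash_seen = False
            if flash > 0.0:
                y_star = y_star_flash
            else:
                # omission: a predicted flash was not delivered
                y_star = ps[PS_Y_LATENT]
                if ps[PS_Y_LATENT] > 0.0:
                    ps[PS_Y_LATENT] = p[P_K] * ps[PS_Y_LATENT]
            # habituation increment
            ps[PS_SINT_RED] *= p[P_GAMMA_B]
            out_ev[n_ev, EV_T] = t
            out_ev[n_ev, EV_BLOCK] = 0.0
            out_ev[n_ev, EV_FLASH] = flash
            out_ev[n_ev, EV_YSTAR_PRE] = y_star
            out_ev[n_ev, EV_Y_POST] = ps[PS_Y_LATENT]
            out_ev[n_ev, EV_SNOV] = 0.5 - abs(ps[PS_Y_LATENT] - 0.5)
            out_ev[n_ev, EV_SINT] = ps[PS_SINT_RED]
            out_ev[n_ev, EV_D_MAX] = cur_d_max if flash > 0.0 else p[P_D_REST]
            out_ev[n_ev, EV_D_MIN] = cur_d_min if flash > 0.0 else p[P_D_REST]
            out_ev[n_ev, EV_W_MOT_D1] = w_mot[0, CH_RED]
            out_ev[n_ev, EV_W_MOT_D2] = w_mot[1, CH_RED]
            out_ev[n_ev, EV_W_SEN_D1] = w_sen[0, CH_RED]
            out_ev[n_ev, EV_W_SEN_D2] = w_sen[1, CH_RED]
            out_ev[n_ev, EV_STOT_RED] = s_tot_red
            if pda and flash == 0.0 and y_star > 0.0:
                event_t = t
                amp_sc = 0.0
                amp_cancel = y_star
                ysq_froz_d1 = ysq[0, CH_RED]
                ysq_froz_d2 = ysq[1, CH_RED]
                ev_x_mot = yout[nw.MCTX, CH_RED]
                ev_x_sen = yout[nw.SCTX, CH_RED]
                ev_y_d1 = yout[nw.D1, CH_RED]
                ev_y_d2 = yout[nw.D2, CH_RED]
                cur_d_max = p[P_D_REST]
                cur_d_min = p[P_D_REST]
                open_row = n_ev
            n_ev += 1

        if complete_white and n_ev < EVENT_CAP:
            ps[PS_SINT_WHITE] *= p[P_GAMMA_B]
            out_ev[n_ev, EV_T] = t
            out_ev[n_ev, EV_BLOCK] = 1.0
            out_ev[n_ev, EV_FLASH] = 0.0
            out_ev[n_ev, EV_YSTAR_PRE] = 0.0
            out_ev[n_ev, EV_Y_POST] = 0.0
            out_ev[n_ev, EV_SNOV] = 0.0
            out_ev[n_ev, EV_SINT] = ps[PS_SINT_WHITE]
            out_ev[n_ev, EV_D_MAX] = p[P_D_REST]
            out_ev[n_ev, EV_D_MIN] = p[P_D_REST]
            out_ev[n_ev, EV_W_MOT_D1] = w_mot[0, CH_RED]
            out_ev[n_ev, EV_W_MOT_D2] = w_mot[1, CH_RED]
            out_ev[n_ev, EV_W_SEN_D1] = w_sen[0, CH_RED]
            out_ev[n_ev, EV_W_SEN_D2] = w_sen[1, CH_RED]
            out_ev[n_ev, EV_STOT_RED] = s_tot_red
            n_ev += 1

        # --- phasic dopamine and gated plasticity -----------------------
        if pda:
            sc = triangular_pulse(t, event_t, p[P_PULSE_W], amp_sc)
            cancel = triangular_pulse(t, event_t, p[P_PULSE_W], amp_cancel)
            i_snc = snc_input(sc, cancel, p[P_A_PLUS], p[P_A_MINUS])
            a_snc += (dt / p[P_TAU_SNC]) * (-a_snc + i_snc)
            d = snc_output(a_snc, p[P_D_REST])
        else:
            d = p[P_D_REST]

        in_window = pda and (t - event_t) < p[P_WINDOW] and (t >= event_t)
        if in_window:
            if d > cur_d_max:
                cur_d_max = d
            if d < cur_d_min:
                cur_d_min = d
            if open_row >= 0:
                out_ev[open_row, EV_D_MAX] = cur_d_max
                out_ev[open_row, EV_D_MIN] = cur_d_min

        if in_window or p[P_TONIC_PLAST] > 0.0:
            if in_window:
                # pre/post rates sampled at event onset (eligibility trace)
                x_mot = ev_x_mot
                x_sen = ev_x_sen
                y_d1 = ev_y_d1
                y_d2 = ev_y_d2
            else:
                x_mot = yout[nw.MCTX, CH_RED]
                x_sen = yout[nw.SCTX, CH_RED]
                y_d1 = yout[nw.D1, CH_RED]
                y_d2 = yout[nw.D2, CH_RED]
            c_d1 = _c_bcm_scalar(d, p[P_AP_D1_HI], p[P_AP_D1_LO],
                                 p[P_AM_D1_HI], p[P_AM_D1_LO],
                                 p[P_TAU_RATIO], p[P_C_GAIN])
            c_d2 = _c_bcm_scalar(d, p[P_AP_D2_HI], p[P_AP_D2_LO],
                                 p[P_AM_D2_HI], p[P_AM_D2_LO],
                                 p[P_TAU_RATIO], p[P_C_GAIN])
            th_d1 = ysq_froz_d1 * c_d1
            th_d2 = ysq_froz_d2 * c_d2
            w_mot[0, CH_RED] = weight_update(w_mot[0, CH_RED], x_mot, y_d1,
                                             th_d1, p[P_ETA], dt,
                                             p[P_W_MIN], p[P_W_MAX])
            w_mot[1, CH_RED] = weight_update(w_mot[1, CH_RED], x_mot, y_d2,
                                             th_d2, p[P_ETA], dt,
                                             p[P_W_MIN], p[P_W_MAX])
            # sensory weights start at zero and may return there: their
            # lower bound is 0, while the motor floor keeps actions performable
            w_sen[0, CH_RED] = weight_update(w_sen[0, CH_RED], x_sen, y_d1,
                                             th_d1, p[P_ETA], dt,
                                             0.0, p[P_W_MAX])
            w_sen[1, CH_RED] = weight_update(w_sen[1, CH_RED], x_sen, y_d2,
                                             th_d2, p[P_ETA], dt,
                                             0.0, p[P_W_MAX])

        # --- <y^2> tracker ----------------------------------------------
        k_ysq = dt / p[P_YSQ_TAU]
        for r in range(2):
            pop = nw.D1 if r == 0 else nw.D2
            for c in range(3):
                yv = yout[pop, c]
                ysq[r, c] += k_ysq * (yv * yv - ysq[r, c])

    return n_ev
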