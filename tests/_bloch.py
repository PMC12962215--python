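"""Independent Bloch-equation steady-state solver used as a bSSFP oracle.

Solves the 3x3 linear fixed point of one TR (instantaneous RF rotation
about x, then free precession with relaxation) in the frame that hops with
the RF phase ramp, and evolves to TE at the off-resonance frequency with
the receiver demodulated at the exciting pulse's phase. Independent of the
closed-form ellipse expression it is used to check.
"""

import numpy as np


def bloch_steady_state_profile(tissue, seq) -> np.ndarray:
    t1, t2 = tissue.t1_ms, tissue.t2_ms
    df, pd = tissue.off_resonance_hz, tissue.proton_density
    tr, te = seq.tr_ms, seq.te_ms
    alpha = np.deg2rad(seq.flip_deg)
    rx = np.array([
        [1.0, 0.0, 0.0],
        [0.0, np.cos(alpha), np.sin(alpha)],
        [0.0, -np.sin(alpha), np.cos(alpha)],
    ])
    e1, e2 = np.exp(-tr / t1), np.exp(-tr / t2)
    out = []
    for dphi in np.deg2rad(seq.rf_phase_increments_deg):
        beta = 2.0 * np.pi * df * tr * 1e-3 - dphi
        rz = np.array([
            [np.cos(beta), -np.sin(beta), 0.0],
            [np.sin(beta), np.cos(beta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        A = np.diag([e2, e2, e1]) @ rz @ rx
        b = np.array([0.0, 0.0, pd * (1.0 - e1)])
        m_minus = np.linalg.solve(np.eye(3) - A, b)
        m_plus = rx @ m_minus
        bte = 2.0 * np.pi * df * te * 1e-3
        out.append(np.exp(-te / t2) * np.exp(1j * bte)
                   * (m_plus[0] + 1j * m_plus[1]))
    return np.asarray(out)
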