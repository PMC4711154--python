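"""Frozen experiment configurations for the figure-level conditions.

Each preset maps to a model name plus keyword overrides of that model's
config dataclass. Names follow the figure panels of the alignment
study: fig1/fig2 are the stochastic pair-difference process under
detailed vs global balance and LTP vs LTD bias, fig3 the single-neuron
simulation, fig4-6 the recurrent network, and the sm variants the
supplementary mechanisms (multiplicative STDP, slow or subtractive
normalization, weight-dependent failure).
"""

from __future__ import annotations

PRESETS: dict[str, dict] = {
    # Kesten pair-difference process
    "fig1c": {"model": "kesten", "balance_mode": "detailed", "ltp_bias": 2.0,
              "failure_prob": 0.2},
    "fig1d": {"model": "kesten", "balance_mode": "global", "ltp_bias": 2.0,
              "failure_prob": 0.2},
    "fig2a": {"model": "kesten", "balance_mode": "detailed", "ltp_bias": 2.0,
              "failure_prob": 0.2},
    "fig2b": {"model": "kesten", "balance_mode": "detailed", "ltp_bias": 0.5,
              "failure_prob": 0.2},
    # single neuron
    "fig3_ltp": {"model": "neuron", "a_minus": 0.00075},
    "fig3_ltd": {"model": "neuron", "a_minus": 0.00125},
    "sm3": {"model": "neuron", "a_minus": 0.00075, "stdp_mode": "multiplicative"},
    "sm4": {"model": "neuron", "a_minus": 0.00075, "norm_mode": "subtractive"},
    "sm4_weight_failure": {"model": "neuron", "a_minus": 0.00075,
                           "failure_mode": "weight_dependent"},
    # recurrent network
    "fig4": {"model": "sorn", "beta": 1.25, "p_fail": 0.2, "n_replicates": 5},
    "fig5": {"model": "sorn", "beta": 1 / 1.25, "p_fail": 0.2, "n_replicates": 5},
    "fig6": {"model": "sorn", "beta": 1.25, "p_fail": 0.2},
    "sm5": {"model": "sorn", "beta": 1.25, "p_fail": 0.2, "eta_sn": 0.1},
    "sm6": {"model": "sorn", "beta": 1.25, "p_fail": 0.2},
}
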