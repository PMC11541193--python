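# Demonstration pipeline: simulated panel, baseline fit, one placebo
# scheme, risk-group heterogeneity, burden accounting and the
# counterfactual-population trend decomposition.
#
#   cyclomort report --config examples/config.yaml --out-dir out
seed: 1
simulate:
  n_states: 20
  n_months: 360
  irf_horizon: 24
  trend_degree: 3
lags:
  n_leads: 12
  n_lags: 24
  cumulative_horizon: 24
controls:
  state_trend_order: 3
placebo:
  schemes: [within_state]
  n_iter: 100
heterogeneity:
  enabled: true
burden:
  horizon: 24
  decompose: true
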