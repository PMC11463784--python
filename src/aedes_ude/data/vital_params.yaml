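# Default biological parameter estimates for the two-stage Aedes model
# (Gaussian survival, Sharpe-DeMichele development, diapause ratio).
mu_p: 1.0000
T_p: 20.7896
V_p: 17.4774
mu_a: 0.6000
T_a: 23.3492
V_a: 19.3648
AA: 0.0150
HA: 28116.4131
HH: 35378.2344
TH: 301.6750
delta: 0.0023
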