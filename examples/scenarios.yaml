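# Uniform-band mean-vector scenarios for analytic power curves.
# The covariance here is the package's self-contained AR(1) default
# (unit variances, rho = 0.5); replace `ar1_rho`/`variance` with an explicit
# `sigma` matrix to use a covariance estimated from your own data.
p_dim: 30
ar1_rho: 0.5
variance: 0.01
alpha: 0.05
n_grid: [16, 20, 30, 40, 50, 60, 80, 100]
scenarios:
  - name: small-difference-no-overlap
    bounds1: [0.1, 0.125]
    bounds2: [0.1251, 0.15]
  - name: small-difference-overlap
    bounds1: [0.2, 0.225]
    bounds2: [0.2125, 0.2375]
  - name: large-difference-no-overlap
    bounds1: [0.1, 0.125]
    bounds2: [0.2, 0.225]
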