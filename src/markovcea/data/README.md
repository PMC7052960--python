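# Bundled data

`fr_male_2017_standin.csv` — period life table (columns `age`, `qx`) used as
the default background-mortality input.  It is **not** the official INED/INSEE
table: it is a Gompertz–Makeham table, `mu(x) = c + a*exp(b*x)` with
`a = 1.93145777e-05`, `b = 0.09817481`, `c = 5e-4`, calibrated so that the
implied life expectancies match published 2017 French male summary values
(79.4 years at birth, 23.2 years at age 60; residual e(70) = 15.5 years).
The table is closed with `qx = 1` at age 110.  Supply the real national table
via the `lifetable` config key or `--lifetable` to replace it.
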