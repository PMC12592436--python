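# Spectral attenuation coefficient of interior Arctic sea ice, m^-1.
# SYNTHETIC stand-in table: representative magnitudes and spectral shape
# (visible minimum near 500 nm, steep near-infrared rise) constructed to
# emulate published field observations; replace with a digitized table of
# the same two-column format for production use.
# wavelength_nm	k_ice_m-1
200	2.50
250	1.90
300	1.50
350	1.20
400	1.00
450	0.85
500	0.80
550	0.90
600	1.10
650	1.40
700	1.90
750	2.60
800	3.60
850	5.00
900	7.00
950	10.0
1000	14.0
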