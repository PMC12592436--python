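# Absorption coefficient of pure sea water, m^-1. SYNTHETIC stand-in table
# with representative magnitudes (clear-water minimum near 420 nm, strong
# near-infrared bands); used only inside the ocean-surface-albedo
# water-leaving reflectance term. Replace with a laboratory table of the
# same two-column format for production use.
# wavelength_nm	a_w_m-1
200	3.00
250	0.600
300	0.140
350	0.0250
380	0.0120
400	0.0066
420	0.0045
440	0.0063
460	0.0090
480	0.0127
500	0.0204
520	0.0410
540	0.0470
560	0.0620
580	0.108
600	0.222
620	0.276
640	0.329
660	0.400
680	0.465
700	0.620
750	2.47
800	2.00
850	4.30
900	6.80
950	39.0
1000	36.0
1100	17.0
1200	104
1300	110
1400	1200
1500	2000
1600	670
1700	580
1800	800
1900	13000
2000	6900
2200	1700
2400	5000
2600	15000
2700	20000
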