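# Chlorophyll-a specific absorption coefficient of phytoplankton,
# m^2 (mg chl)^-1. SYNTHETIC stand-in table: blue (440 nm) and red (675 nm)
# absorption peaks with representative magnitudes for Arctic assemblages,
# constructed to emulate published absorption spectra; replace with a
# digitized table of the same two-column format for production use.
# wavelength_nm	a_phy_star_m2_per_mg
300	0.0100
320	0.0120
340	0.0140
360	0.0160
380	0.0200
400	0.0260
420	0.0310
440	0.0350
460	0.0310
480	0.0250
500	0.0180
520	0.0120
540	0.0080
560	0.0060
580	0.0050
600	0.0050
620	0.0060
640	0.0080
660	0.0150
670	0.0190
680	0.0180
690	0.0100
700	0.0050
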