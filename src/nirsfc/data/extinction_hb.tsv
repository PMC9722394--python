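# Molar extinction coefficients of human hemoglobin, cm^-1 / (mol/L).
# Values from the widely used compilation by S. Prahl (Oregon Medical Laser
# Center), based on the data of W. B. Gratzer and N. Kollias; identical table
# is used for the forward (simulation) and inverse (MBLL) directions.
wavelength_nm	eps_hbo	eps_hbr
730	390.0	1102.2
850	1058.0	691.32
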