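# Silver (Ag) optical constants, P. B. Johnson and R. W. Christy,
# Phys. Rev. B 6, 4370 (1972). Columns: wavelength_nm, n, k
# (complex refractive index n + ik, time convention e^{-i omega t}).
# Wavelengths converted from the published photon energies via
# lambda_nm = 1239.84193 / E_eV, listed in increasing wavelength.
wavelength_nm,n,k
187.85,1.07,1.212
191.33,1.10,1.232
195.25,1.12,1.255
199.01,1.14,1.277
203.25,1.15,1.296
207.33,1.18,1.312
211.58,1.20,1.325
216.38,1.22,1.336
221.00,1.25,1.342
226.25,1.26,1.344
231.31,1.28,1.357
237.06,1.28,1.367
242.63,1.30,1.378
248.96,1.31,1.389
255.11,1.33,1.393
261.57,1.35,1.387
268.95,1.38,1.372
276.13,1.41,1.331
284.37,1.41,1.264
292.42,1.39,1.161
300.93,1.34,0.964
310.74,1.13,0.616
320.37,0.81,0.392
331.51,0.17,0.829
342.50,0.14,1.142
354.24,0.10,1.419
367.91,0.07,1.657
381.49,0.05,1.864
397.39,0.05,2.070
413.28,0.05,2.275
430.50,0.04,2.462
450.85,0.04,2.657
471.42,0.05,2.869
495.94,0.05,3.093
520.94,0.05,3.324
548.60,0.06,3.586
582.09,0.05,3.858
616.84,0.06,4.152
659.49,0.05,4.483
704.46,0.04,4.838
755.99,0.03,5.242
821.09,0.04,5.727
892.69,0.04,6.312
984.00,0.04,6.992
1087.58,0.04,7.795
1215.53,0.09,8.828
1393.08,0.13,10.10
1610.18,0.15,11.85
1937.25,0.24,14.08
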