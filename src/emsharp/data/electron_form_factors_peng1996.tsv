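# Electron scattering factors, 5-Gaussian parameterization (Peng et al. 1996,
# Acta Cryst. A52, 257; International Tables for Crystallography C, 4.3.2.2).
# f(q) = sum_i a_i * exp(-b_i * q^2) with q = sin(theta)/lambda = s/2 in 1/A.
# version: 1
element	a1	b1	a2	b2	a3	b3	a4	b4	a5	b5
H	0.0349	0.5347	0.1201	3.5867	0.1970	12.3471	0.0573	18.9525	0.1195	38.6269
C	0.0893	0.2465	0.2563	1.7100	0.7570	6.4094	1.0487	18.6113	0.3575	50.2523
N	0.1022	0.2451	0.3219	1.7481	0.7982	6.1925	0.8197	17.3894	0.1715	48.1431
O	0.0974	0.2067	0.2921	1.3815	0.6910	4.6943	0.6990	12.7105	0.2039	32.4726
S	0.2497	0.2681	0.5628	1.6711	1.3899	7.0267	2.1865	19.5377	0.7715	50.3888
P	0.2548	0.2908	0.6106	1.8740	1.4541	8.5176	2.3204	24.3434	0.8477	63.2996
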