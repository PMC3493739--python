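Name	Klinefelter syndrome-std	Healthy control-std	Fold change (log2 ratio)	P-value
hsa-miR-451a	7844.0913	2482.9131	−1.65957256	0
hsa-miR-486	3190.7976	743.1139	−2.10226184	0
hsa-miR-27a	455.2549	982.3593	1.10957624	0
hsa-miR-144	320.4484	112.562	−1.5093722	1.57E-222
hsa-miR-181a-2	276.7135	609.6767	1.13965138	1.65E-273
hsa-miR-142	262.1009	537.0231	1.03486184	1.68E-206
hsa-miR-27b	215.5875	572.122	1.40804929	0
hsa-miR-4732	50.7325	6.3444	−2.99935462	4.17E-85
hsa-miR-181a	48.8802	129.1393	1.40160602	2.05E-81
hsa-miR-31	35.1938	107.6502	1.6129578	1.67E-83
hsa-miR-122	33.3415	71.528	1.10118909	5.80E-32
hsa-miR-1255a	32.5182	12.8935	−1.33460346	2.65E-20
hsa-miR-95	28.2991	59.3509	1.06851374	1.35E-25
hsa-miR-144	22.4334	45.9458	1.0342847	3.31E-19
hsa-miR-361	19.4492	46.8667	1.2688524	1.61E-26
hsa-miR-182	15.23	4.8095	−1.66295712	1.11E-13
hsa-miR-532	11.7313	35.6105	1.6019398	1.76E-28
hsa-miR-324	10.4964	23.638	1.17121337	1.26E-12
hsa-miR-34c	8.747	19.2379	1.13709112	4.06E-10
hsa-miR-369	7.4092	3.5815	−1.04875384	0.000291414
hsa-miR-1271	7.2034	15.1447	1.07206308	1.25E-07
hsa-miR-99a	6.7918	28.9591	2.09215089	4.44E-33
hsa-miR-365b	6.0714	1.8419	−1.72083449	1.75E-06
hsa-let-7i	5.8656	13.9168	1.24647692	1.10E-08
hsa-miR-329	5.8656	2.1489	−1.44868034	3.38E-05
hsa-miR-1306	4.7337	9.9259	1.06822964	2.04E-05
hsa-miR-193b	4.7337	12.2795	1.37521164	7.10E-09
hsa-miR-654	4.7337	2.2512	−1.07227404	0.003290144
hsa-miR-125b	4.6308	14.4284	1.63957797	8.65E-13
hsa-miR-449c	4.5279	0.8186	−2.46761152	2.13E-07
hsa-miR-873	4.322	9.5166	1.13874716	1.12E-05
hsa-miR-186	4.1162	12.3818	1.58883607	9.69E-11
hsa-miR-4433	3.6017	1.7396	−1.0499224	0.011952811
hsa-miR-454	3.6017	1.7396	−1.0499224	0.011952811
hsa-miR-548w	3.4988	8.1863	1.22635134	1.58E-05
hsa-miR-146b	3.3959	9.8236	1.53245784	2.04E-08
hsa-miR-151b	3.293	7.163	1.12116143	0.000171603
hsa-miR-548ak	3.293	7.9817	1.27729354	1.08E-05
hsa-miR-100	2.6755	6.7537	1.33586957	2.84E-05
hsa-miR-206	2.6755	64.979	4.60209311	2.00E-152
hsa-miR-874	2.5726	10.3352	2.00626724	3.88E-12
hsa-miR-548o	2.4697	5.0141	1.02165496	0.003642313
hsa-miR-140	2.3668	4.8095	1.02294912	0.004378249
hsa-miR-3934	2.161	5.4234	1.32749851	0.000193986
hsa-miR-196a	2.0581	6.4467	1.64724777	1.80E-06
hsa-miR-3614	1.9552	5.2188	1.41640192	0.000123491
hsa-miR-365a	1.7494	3.5815	1.03370374	0.013404561
hsa-miR-365b	1.7494	3.5815	1.03370374	0.013404561
hsa-miR-4425	1.7494	4.5025	1.36386608	0.000539221
hsa-miR-1256	1.6465	3.5815	1.12116143	0.008265541
hsa-miR-215	1.6465	4.8095	1.54648441	8.48E-05
hsa-miR-320d	1.6465	3.4792	1.0793531	0.011616255
hsa-miR-3158	1.5436	0.307	−2.32998839	0.004261655
hsa-miR-337	1.5436	0.4093	−1.91506838	0.011408876
hsa-miR-769	1.5436	3.3769	1.12940051	0.009947674
hsa-miR-4750	1.4407	0.5116	−1.49368178	0.040158862
hsa-miR-1273c	1.3378	3.5815	1.42070149	0.001500021
hsa-miR-3136	1.3378	3.4792	1.37889316	0.002226957
hsa-miR-3609	1.3378	0.2047	−2.70827944	0.004039068
hsa-miR-369	1.2349	2.5582	1.05073484	0.035018005
hsa-miR-5091	1.2349	2.8652	1.21424163	0.012106435
hsa-miR-876	1.2349	3.5815	1.53616972	0.000768989
hsa-miR-200b	1.132	2.3536	1.05599519	0.042625027
hsa-miR-1246	1.0291	0.2047	−2.32980017	0.021878979
hsa-miR-3613	1.0291	4.4002	2.09618592	3.73E-06
hsa-miR-378d	1.0291	6.0374	2.55254421	9.22E-10
hsa-miR-582	0.9262	2.7629	1.57678768	0.002709278
hsa-miR-873	0.9262	2.1489	1.21420269	0.030629647
hsa-miR-99b	0.9262	4.1955	2.17944709	3.72E-06
hsa-miR-141	0.8232	2.4559	1.57693693	0.004783616
hsa-miR-31	0.7203	2.1489	1.57692854	0.008496598
hsa-miR-3917	0.7203	2.6606	1.88508182	0.000870192
hsa-miR-548i	0.7203	2.8652	1.99196604	0.000332941
hsa-miR-671	0.7203	1.7396	1.2720858	0.044754756
hsa-miR-200a	0.6174	2.8652	2.21435846	0.000124782
hsa-miR-509-3	0.6174	2.3536	1.93059176	0.00150729
hsa-miR-3179	0.5145	1.4326	1.47739286	0.042651583
hsa-miR-1298	0.4116	1.3303	1.69243674	0.031813773
hsa-miR-188	0.4116	1.7396	2.07944073	0.004523166
hsa-miR-548h	0.4116	1.7396	2.07944073	0.004523166
hsa-miR-577	0.4116	1.3303	1.69243674	0.031813773
hsa-miR-375	0.3087	1.5349	2.31386728	0.004594046
hsa-miR-4736	0.3087	1.1256	1.86641685	0.036103136
hsa-miR-1468	0.2058	1.5349	2.89882978	0.001365699
hsa-miR-4716	0.2058	1.4326	2.79932096	0.002438799
hsa-miR-548ai	0.2058	1.1256	2.45137935	0.013318743
hsa-miR-570	0.2058	1.1256	2.45137935	0.013318743
hsa-miR-125b-2	0.1029	2.1489	4.38428346	6.07E-06
hsa-miR-330	0.01	1.1256	6.81455042	0.000505
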