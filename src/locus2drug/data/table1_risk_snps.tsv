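rsid	region	p	or	ci_low	ci_high
rs10505477	8q24.2	9E-7	1.13	1.08	1.19
rs6983267	8q24.2	8E-28	1.2	1.16	1.24
rs4939827	18q21.1	1E-9	1.06	1.03	1.09
rs10795668	10p14	4E-6	1.27	1.14	1.40
rs16892766	8q23	2E-7	1.14	1.08	1.19
rs3802842	11q23.1	8E-7	1.18	1.11	1.27
rs4779584	15q13	1E-7	1.14	1.08	1.18
rs4939827	18q21.1	8E-9	1.28	1.18	1.39
rs4939827	18q21.1	2E-8	1.18	1.11	1.25
rs6983267	8q24.2	6E-10	1.11	1.08	1.15
rs7014346	8q24.2	3E-13	1.12	1.10	1.16
rs10411210	19q13.1	2E-7	1.14	1.06	1.19
rs4444235	14q22	7E-10	1.07	1.04	1.10
rs961253	20p12	1E-14	1.27	1.16	1.39
rs9929218	16q22	3E-11	1.17	1.12	1.23
rs10936599	3q26.2	4E-8	1.35	1.20	1.49
rs11169552	12q13.1	3E-6	1.47	1.25	1.72
rs4925386	20q13.3	4E-7	1.24	1.14	1.34
rs6687758	1q41	2E-10	1.12	1.08	1.16
rs6691170	1q41	1E-8	1.1	1.06	1.12
rs6983267	8q24.2	9E-26	1.19	1.15	1.23
rs7758229	6q25.3	7E-11	1.24	1.17	1.33
rs11632715	15q13.3	3E-6	1.37	1.20	1.56
rs16969681	15q13.3	9E-7	1.13	1.08	1.19
rs1957636	14q22.2	2E-10	1.12	1.09	1.16
rs16892766	8q23	4E-10	1.17	1.11	1.22
rs3802842	11q23.1	3E-6	1.13	1.08	1.20
rs4779584	15q13	2E-10	1.12		
rs4939827	18q21.1	6E-6	1.11	1.06	1.15
rs7315438	12q24.2	3E-18	1.27	1.20	1.34
rs1321311	6p21.2	1E-10	1.11	1.08	1.15
rs3824999	11q13.4	1E-10	1.1	1.07	1.13
rs5934683	Xp22.2	2E-10	1.09	1.05	1.11
rs7972465	12q13.13	8E-7	1.18	1.11	1.27
rs10911251	1q25	2E-6	1.28	1.16	1.43
rs11903757	2q32.3	3E-6	1.06	0.88	1.29
rs13130787	4q22	3E-8	1.09	1.06	1.13
rs17094983	14q23	1E-11	1.13	1.09	1.18
rs1912453	1q23	5E-7	1.12	1.08	1.19
rs2057314	6q22.1	7E-6	1.1	1.05	1.14
rs2128382	8q24.2	4E-8	1.16	1.10	1.22
rs3217810	12p13.3	9E-6	1.07	1.04	1.11
rs3217901	12p13.3	3E-7	1.09	1.06	1.13
rs3802842	11q23.1	8E-6	1.11	1.06	1.16
rs4779584	15q13	5E-8	1.18	1.11	1.25
rs4813802	20p12	2E-8	1.18	1.11	1.24
rs4939827	18q21.1	4E-7	1.14	1.08	1.20
rs59336	12q24.2	3E-8	1.04	1.04	1.10
rs6983267	8q24.2	8E-10	1.11	1.08	1.15
rs10774214	12p13.3	2E-6	1.28	1.15	1.41
rs10774214	12p13.3	3E-6	1.28	1.12	1.42
rs1665650	10q25.3	5E-10	1.17	1.11	1.23
rs2423279	20p12	6E-8	1.2	1.12	1.28
rs647161	5q31.1	2E-9	1.09	1.06	1.12
rs10114408	9q22.3	5E-10	1.17	1.11	1.23
rs10879357	12q21.1	4E-6	1.27	1.15	1.41
rs17730929	4q13.2	4E-7	1.11	1.06	1.15
rs367615	5q21	3E-6	1.08	1.04	1.11
rs39453	7p15.3	4E-10	1.08	1.05	1.10
rs4591517	3p24.3	1E-9	1.08	1.06	1.11
rs9365723	6q25.3	1E-12	1.16	1.09	1.27
rs12548021	8p12	3E-6	1.25	1.14	1.39
rs3104964	8q22.1	4E-7	1.09	1.06	1.13
rs8180040	3p21.3	5E-7	1.23	1.14	1.34
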