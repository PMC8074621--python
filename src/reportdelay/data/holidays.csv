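date,federal,christian,muslim,jewish,hindu,celebration
2012-01-01,1,0,0,0,0,0
2012-01-16,1,0,0,0,0,0
2012-02-14,0,0,0,0,0,1
2012-02-20,1,0,0,0,0,0
2012-03-08,0,0,0,0,1,0
2012-03-17,0,0,0,0,0,1
2012-04-06,0,1,0,0,0,0
2012-04-07,0,0,0,1,0,0
2012-04-08,0,1,0,0,0,0
2012-05-05,0,0,0,0,0,1
2012-05-28,1,0,0,0,0,0
2012-07-04,1,0,0,0,0,0
2012-08-19,0,0,1,0,0,0
2012-09-03,1,0,0,0,0,0
2012-09-17,0,0,0,1,0,0
2012-09-26,0,0,0,1,0,0
2012-10-08,1,0,0,0,0,0
2012-10-26,0,0,1,0,0,0
2012-10-31,0,0,0,0,0,1
2012-11-11,1,0,0,0,0,0
2012-11-13,0,0,0,0,1,0
2012-11-22,1,0,0,0,0,0
2012-12-25,1,1,0,0,0,0
2012-12-31,0,0,0,0,0,1
2013-01-01,1,0,0,0,0,0
2013-01-21,1,0,0,0,0,0
2013-02-14,0,0,0,0,0,1
2013-02-18,1,0,0,0,0,0
2013-03-17,0,0,0,0,0,1
2013-03-26,0,0,0,1,0,0
2013-03-27,0,0,0,0,1,0
2013-03-29,0,1,0,0,0,0
2013-03-31,0,1,0,0,0,0
2013-05-05,0,0,0,0,0,1
2013-05-27,1,0,0,0,0,0
2013-07-04,1,0,0,0,0,0
2013-08-08,0,0,1,0,0,0
2013-09-02,1,0,0,0,0,0
2013-09-05,0,0,0,1,0,0
2013-09-14,0,0,0,1,0,0
2013-10-14,1,0,0,0,0,0
2013-10-15,0,0,1,0,0,0
2013-10-31,0,0,0,0,0,1
2013-11-03,0,0,0,0,1,0
2013-11-11,1,0,0,0,0,0
2013-11-28,1,0,0,0,0,0
2013-12-25,1,1,0,0,0,0
2013-12-31,0,0,0,0,0,1
2014-01-01,1,0,0,0,0,0
2014-01-20,1,0,0,0,0,0
2014-02-14,0,0,0,0,0,1
2014-02-17,1,0,0,0,0,0
2014-03-17,0,0,0,0,1,1
2014-04-15,0,0,0,1,0,0
2014-04-18,0,1,0,0,0,0
2014-04-20,0,1,0,0,0,0
2014-05-05,0,0,0,0,0,1
2014-05-26,1,0,0,0,0,0
2014-07-04,1,0,0,0,0,0
2014-07-28,0,0,1,0,0,0
2014-09-01,1,0,0,0,0,0
2014-09-25,0,0,0,1,0,0
2014-10-04,0,0,1,1,0,0
2014-10-13,1,0,0,0,0,0
2014-10-23,0,0,0,0,1,0
2014-10-31,0,0,0,0,0,1
2014-11-11,1,0,0,0,0,0
2014-11-27,1,0,0,0,0,0
2014-12-25,1,1,0,0,0,0
2014-12-31,0,0,0,0,0,1
2015-01-01,1,0,0,0,0,0
2015-01-19,1,0,0,0,0,0
2015-02-14,0,0,0,0,0,1
2015-02-16,1,0,0,0,0,0
2015-03-06,0,0,0,0,1,0
2015-03-17,0,0,0,0,0,1
2015-04-03,0,1,0,0,0,0
2015-04-04,0,0,0,1,0,0
2015-04-05,0,1,0,0,0,0
2015-05-05,0,0,0,0,0,1
2015-05-25,1,0,0,0,0,0
2015-07-04,1,0,0,0,0,0
2015-07-17,0,0,1,0,0,0
2015-09-07,1,0,0,0,0,0
2015-09-14,0,0,0,1,0,0
2015-09-23,0,0,1,1,0,0
2015-10-12,1,0,0,0,0,0
2015-10-31,0,0,0,0,0,1
2015-11-11,1,0,0,0,1,0
2015-11-26,1,0,0,0,0,0
2015-12-25,1,1,0,0,0,0
2015-12-31,0,0,0,0,0,1
2016-01-01,1,0,0,0,0,0
2016-01-18,1,0,0,0,0,0
2016-02-14,0,0,0,0,0,1
2016-02-15,1,0,0,0,0,0
2016-03-17,0,0,0,0,0,1
2016-03-24,0,0,0,0,1,0
2016-03-25,0,1,0,0,0,0
2016-03-27,0,1,0,0,0,0
2016-04-23,0,0,0,1,0,0
2016-05-05,0,0,0,0,0,1
2016-05-30,1,0,0,0,0,0
2016-07-04,1,0,0,0,0,0
2016-07-06,0,0,1,0,0,0
2016-09-05,1,0,0,0,0,0
2016-09-11,0,0,1,0,0,0
2016-10-03,0,0,0,1,0,0
2016-10-10,1,0,0,0,0,0
2016-10-12,0,0,0,1,0,0
2016-10-30,0,0,0,0,1,0
2016-10-31,0,0,0,0,0,1
2016-11-11,1,0,0,0,0,0
2016-11-24,1,0,0,0,0,0
2016-12-25,1,1,0,0,0,0
2016-12-31,0,0,0,0,0,1
2017-01-01,1,0,0,0,0,0
2017-01-16,1,0,0,0,0,0
2017-02-14,0,0,0,0,0,1
2017-02-20,1,0,0,0,0,0
2017-03-13,0,0,0,0,1,0
2017-03-17,0,0,0,0,0,1
2017-04-11,0,0,0,1,0,0
2017-04-14,0,1,0,0,0,0
2017-04-16,0,1,0,0,0,0
2017-05-05,0,0,0,0,0,1
2017-05-29,1,0,0,0,0,0
2017-06-25,0,0,1,0,0,0
2017-07-04,1,0,0,0,0,0
2017-09-01,0,0,1,0,0,0
2017-09-04,1,0,0,0,0,0
2017-09-21,0,0,0,1,0,0
2017-09-30,0,0,0,1,0,0
2017-10-09,1,0,0,0,0,0
2017-10-19,0,0,0,0,1,0
2017-10-31,0,0,0,0,0,1
2017-11-11,1,0,0,0,0,0
2017-11-23,1,0,0,0,0,0
2017-12-25,1,1,0,0,0,0
2017-12-31,0,0,0,0,0,1
2018-01-01,1,0,0,0,0,0
2018-01-15,1,0,0,0,0,0
2018-02-14,0,0,0,0,0,1
2018-02-19,1,0,0,0,0,0
2018-03-02,0,0,0,0,1,0
2018-03-17,0,0,0,0,0,1
2018-03-30,0,1,0,0,0,0
2018-03-31,0,0,0,1,0,0
2018-04-01,0,1,0,0,0,0
2018-05-05,0,0,0,0,0,1
2018-05-28,1,0,0,0,0,0
2018-06-15,0,0,1,0,0,0
2018-07-04,1,0,0,0,0,0
2018-08-21,0,0,1,0,0,0
2018-09-03,1,0,0,0,0,0
2018-09-10,0,0,0,1,0,0
2018-09-19,0,0,0,1,0,0
2018-10-08,1,0,0,0,0,0
2018-10-31,0,0,0,0,0,1
2018-11-07,0,0,0,0,1,0
2018-11-11,1,0,0,0,0,0
2018-11-22,1,0,0,0,0,0
2018-12-25,1,1,0,0,0,0
2018-12-31,0,0,0,0,0,1
2019-01-01,1,0,0,0,0,0
2019-01-21,1,0,0,0,0,0
2019-02-14,0,0,0,0,0,1
2019-02-18,1,0,0,0,0,0
2019-03-17,0,0,0,0,0,1
2019-03-21,0,0,0,0,1,0
2019-04-19,0,1,0,0,0,0
2019-04-20,0,0,0,1,0,0
2019-04-21,0,1,0,0,0,0
2019-05-05,0,0,0,0,0,1
2019-05-27,1,0,0,0,0,0
2019-06-04,0,0,1,0,0,0
2019-07-04,1,0,0,0,0,0
2019-08-11,0,0,1,0,0,0
2019-09-02,1,0,0,0,0,0
2019-09-30,0,0,0,1,0,0
2019-10-09,0,0,0,1,0,0
2019-10-14,1,0,0,0,0,0
2019-10-27,0,0,0,0,1,0
2019-10-31,0,0,0,0,0,1
2019-11-11,1,0,0,0,0,0
2019-11-28,1,0,0,0,0,0
2019-12-25,1,1,0,0,0,0
2019-12-31,0,0,0,0,0,1
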